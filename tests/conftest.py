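import numpy as np
import pandas as pd
import pytest

from mirisk.config import PipelineConfig, SimConfig
from mirisk.containers import ClinicalTable, ExpressionMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_expression():
    """5 features x 6 samples, continuous values."""
    g = np.random.default_rng(7)
    df = pd.DataFrame(
        g.lognormal(2.0, 0.5, size=(5, 6)),
        index=[f"mir-{i}" for i in range(5)],
        columns=[f"S{j}" for j in range(6)],
    )
    return ExpressionMatrix(df, kind="normalized")


@pytest.fixture
def small_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{j}" for j in range(6)],
                "os_days": [100.0, 400.0, 29.0, 31.0, np.nan, 800.0],
                "os_event": [1, 0, 1, 1, np.nan, 0],
                "sample_type": ["TP", "TP", "TP", "TP", "NT", "TP"],
                "stage": ["I", "II", "I", "III", pd.NA, "II"],
                "age": [60, 70, 55, 65, 58, 72],
                "sex": ["male", "female", "male", "female", "male", "female"],
                "batch": ["train"] * 6,
                "treatment": ["none", "chemotherapy", "none", "none", "none", "carboplatin"],
            }
        )
    )


@pytest.fixture(scope="session")
def survival_cohort():
    """n=300 exponential survival with a real binary risk factor."""
    g = np.random.default_rng(11)
    n = 300
    x = g.integers(0, 2, n)
    t_ev = g.exponential(1.0 / (2e-3 * np.exp(0.8 * x)))
    t_c = g.exponential(700.0, n)
    time = np.minimum(t_ev, t_c) + 0.5
    event = (t_ev <= t_c).astype(int)
    return time, event, x


@pytest.fixture(scope="session")
def tiny_sim_config():
    """A small but complete simulated study, quick to generate."""
    return SimConfig(
        n_tumor=150,
        n_normal=30,
        m_mirna=60,
        g_genes=400,
        n_signature=4,
        n_null_regulators=12,
        pairs_per_signature=3,
        beta_range=(0.8, 1.2),
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim_config):
    from mirisk.simulate import generate_cohort

    return generate_cohort(tiny_sim_config)


@pytest.fixture
def pipeline_config():
    return PipelineConfig(importance_repeats=25, seed=3)
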