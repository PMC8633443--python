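"""Pipeline and simulator configuration.

PipelineConfig carries the analysis constants (significance thresholds,
repeat counts, filter fractions); SimConfig the generative parameters of
the synthetic cohorts. Both validate on construction and round-trip
through YAML/dict.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .containers import ValidationError


def _check_prob(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValidationError(f"{name} must lie in (0, 1), got {value}")


@dataclass
class PipelineConfig:
    """Analysis constants.

    Defaults are the published thresholds: DE significance at BH-adjusted
    p < 1e-3 with |log2FC| >= 1, negative-regulation pairs at adjusted
    p < 0.01, over-representation and the univariate survival screen at
    0.05, B = 5000 importance repeats clustered into k = 3 groups, a
    30-day minimum follow-up, a 90% zero-fraction feature filter, and
    discrimination evaluated at 1/3/5 years.
    """

    de_adj_p: float = 1e-3
    de_abs_log2fc: float = 1.0
    pair_adj_p: float = 0.01
    ora_adj_p: float = 0.05
    screen_p: float = 0.05
    screen_adjust: str = "none"  # "none" (raw log-rank p) or "BH"
    importance_repeats: int = 5000
    cluster_k: int = 3
    min_group_frac: float = 0.1
    min_os_days: float = 30.0
    max_zero_frac: float = 0.9
    seed: int = 0
    eval_years: list[float] = field(default_factory=lambda: [1.0, 3.0, 5.0])

    def __post_init__(self) -> None:
        if self.screen_adjust not in ("none", "BH"):
            raise ValidationError("screen_adjust must be 'none' or 'BH'")
        for name in ("de_adj_p", "pair_adj_p", "ora_adj_p", "screen_p"):
            _check_prob(name, getattr(self, name))
        if not (0.0 < self.min_group_frac <= 0.5):
            raise ValidationError("min_group_frac must lie in (0, 0.5]")
        if self.importance_repeats < 1:
            raise ValidationError("importance_repeats must be >= 1")
        if self.cluster_k < 2:
            raise ValidationError("cluster_k must be >= 2")
        if not (0.0 <= self.max_zero_frac <= 1.0):
            raise ValidationError("max_zero_frac must lie in [0, 1]")
        if any(t <= 0 for t in self.eval_years):
            raise ValidationError("eval_years must be positive")

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the root seed.

        Uses a content hash of the stage name (process-stable, unlike
        built-in ``hash``).
        """
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimConfig:
    """Synthetic-cohort generative parameters.

    Defaults emulate a TCGA-scale tumor cohort: ~500 tumor and ~50 normal
    samples, a few hundred miRNAs with 8 planted prognostic ones acting
    through expression thresholds under proportional hazards, exponential
    event times (baseline 5e-5 / day for a patient on the risky side of
    no threshold) with independent exponential censoring tuned to
    roughly 40% censored, negatively regulated miRNA->gene pairs (both
    prognostic miRNAs and null regulators, some co-expressed with a
    prognostic partner), and DE genes between tumor and normal tissue
    with negative-binomial counts.
    """

    n_tumor: int = 500
    n_normal: int = 50
    m_mirna: int = 200
    g_genes: int = 2000
    n_signature: int = 8
    beta_range: tuple[float, float] = (0.5, 1.0)
    threshold_quantile: float = 0.5
    frac_de_genes: float = 0.2
    de_log2fc: float = 2.0
    pairs_per_signature: int = 5
    n_null_regulators: int = 40
    frac_coexpressed: float = 0.5
    coexpression_rho: float = 0.7
    regulation_slope: float = -1.0
    regulation_noise_sd: float = 0.5
    baseline_hazard: float = 5e-5
    censor_rate: float = 6.25e-4
    batch_shift: float = 0.0
    batch_scale: float = 1.0
    stage_risk_gradient: float = 1.0
    nb_dispersion: float = 0.2
    chemo_frac: float = 0.3
    chemo_hr_low_risk: float = 1.0
    chemo_hr_high_risk: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature > self.m_mirna:
            raise ValidationError("n_signature cannot exceed m_mirna")
        if self.n_signature + self.n_null_regulators > self.m_mirna:
            raise ValidationError("signature + null regulators cannot exceed m_mirna")
        lo, hi = self.beta_range
        if not (0.0 <= lo <= hi <= 3.0):
            raise ValidationError("beta_range must satisfy 0 <= low <= high <= 3")
        if self.regulation_slope >= 0:
            raise ValidationError("regulation_slope must be negative")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValidationError("hazard rates must be positive")
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ValidationError("threshold_quantile must lie in (0, 1)")
        if self.batch_scale <= 0:
            raise ValidationError("batch_scale must be positive")
        if not (0.0 <= self.frac_de_genes <= 1.0):
            raise ValidationError("frac_de_genes must lie in [0, 1]")
        if not (0.0 <= self.frac_coexpressed <= 1.0):
            raise ValidationError("frac_coexpressed must lie in [0, 1]")
        if not (-1.0 < self.coexpression_rho < 1.0):
            raise ValidationError("coexpression_rho must lie in (-1, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_range"] = list(self.beta_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "beta_range" in d:
            d["beta_range"] = tuple(d["beta_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)
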