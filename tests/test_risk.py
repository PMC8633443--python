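"""Threshold/beta risk model: cutpoint search, coefficients, the
piecewise score, fitting and transfer."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirisk.containers import ClinicalTable, ExpressionMatrix, ValidationError
from mirisk.risk import (
    SignatureEntry,
    SignatureModel,
    apply_model,
    beta_at_threshold,
    candidate_cutpoints,
    fit_risk_model,
    optimal_threshold,
    score_matrix,
    score_sample,
)
from mirisk.survival import logrank_statistic


def brute_force_threshold(x, time, event, min_group_frac):
    """Definition-level oracle: scan every admissible midpoint."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    uniq = np.unique(x)
    best, best_stat = None, -np.inf
    for c in 0.5 * (uniq[:-1] + uniq[1:]):
        n_hi = (x > c).sum()
        if min(n_hi, n - n_hi) < min_group_frac * n:
            continue
        s = logrank_statistic(time, event, (x > c).astype(int))
        if s > best_stat:
            best, best_stat = c, s
    return best, best_stat


class TestOptimalThreshold:
    def test_matches_bruteforce_on_random_inputs(self):
        g = np.random.default_rng(0)
        for _ in range(50):
            n = 60
            x = g.normal(size=n)
            t_ev = g.exponential(100 * np.exp(-0.8 * (x > 0)), n)
            t_c = g.exponential(150, n)
            time, event = np.minimum(t_ev, t_c) + 0.1, (t_ev <= t_c).astype(int)
            if event.sum() == 0:
                continue
            theta, stat = optimal_threshold(x, time, event, 0.1)
            _, stat_bf = brute_force_threshold(x, time, event, 0.1)
            assert stat == pytest.approx(stat_bf, abs=1e-10)

    def test_two_point_expression_single_candidate(self):
        g = np.random.default_rng(1)
        x = np.array([0.0, 1.0] * 10)
        time = g.exponential(50, 20) + 1
        event = np.ones(20, int)
        theta, _ = optimal_threshold(x, time, event, 0.1)
        assert theta == pytest.approx(0.5)

    def test_min_group_frac_respected(self):
        x = np.concatenate([np.zeros(18), np.arange(1, 3.0)])
        cuts = candidate_cutpoints(x, 0.25)
        for c in cuts:
            assert min((x > c).sum(), (x <= c).sum()) >= 0.25 * len(x)

    def test_planted_threshold_recovered(self):
        """A miRNA acting through a median threshold with |beta| = 1.5 is
        localized within the central quantile band in most seeds."""
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 400
            x = g.lognormal(2.0, 0.5, n)
            theta_true = float(np.exp(2.0))
            risky = x > theta_true
            t_ev = g.exponential(1.0 / (1e-3 * np.exp(1.5 * risky)))
            t_c = g.exponential(600.0, n)
            time, event = np.minimum(t_ev, t_c) + 0.1, (t_ev <= t_c).astype(int)
            theta, _ = optimal_threshold(x, time, event, 0.1)
            q = (x < theta).mean()
            hits += 0.4 < q < 0.6
        assert hits >= 16

    def test_no_admissible_cutpoint_is_error(self):
        time = np.arange(1.0, 13.0)
        event = np.ones(12, int)
        with pytest.raises(ValidationError):
            optimal_threshold(np.ones(12), time, event, 0.1)


class TestBetaAtThreshold:
    def test_sign_convention_hazardous_high(self):
        g = np.random.default_rng(2)
        n = 500
        x = g.normal(size=n)
        risky = x > 0
        t_ev = g.exponential(1.0 / (1e-3 * np.exp(1.0 * risky)))
        t_c = g.exponential(700.0, n)
        time, event = np.minimum(t_ev, t_c) + 0.1, (t_ev <= t_c).astype(int)
        beta = beta_at_threshold(x, 0.0, time, event)
        assert beta > 0

    def test_duplicated_data_symmetric_groups_beta_zero(self):
        time = np.tile(np.arange(1.0, 21.0), 2)
        event = np.tile(np.array([1, 0] * 10), 2)
        x = np.concatenate([np.zeros(20), np.ones(20)])
        beta = beta_at_threshold(x, 0.5, time, event)
        assert abs(beta) < 1e-6

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            beta_at_threshold(np.ones(20), 2.0, np.arange(1.0, 21.0), np.ones(20, int))


MODEL = SignatureModel(
    entries=[SignatureEntry("mir-a", 1.0, -0.5), SignatureEntry("mir-b", 2.0, 0.8)],
    cutoff=0.6,
    expression_scale="test",
)


class TestScoreSample:
    def test_both_risky_branches(self):
        assert score_sample(MODEL, {"mir-a": 0.5, "mir-b": 3.0}) == pytest.approx(1.3)

    def test_both_safe_branches(self):
        assert score_sample(MODEL, {"mir-a": 1.5, "mir-b": 1.0}) == 0.0

    def test_boundary_values_score_zero(self):
        # strict inequalities: sitting exactly on the threshold contributes 0
        assert score_sample(MODEL, {"mir-a": 1.0, "mir-b": 2.0}) == 0.0

    def test_zero_beta_never_contributes(self):
        m = SignatureModel([SignatureEntry("m", 1.0, 0.0)], cutoff=0.0)
        assert score_sample(m, {"m": -5.0}) == 0.0
        assert score_sample(m, {"m": 5.0}) == 0.0

    def test_missing_mirna_is_error(self):
        with pytest.raises(ValidationError, match="mir-b"):
            score_sample(MODEL, {"mir-a": 0.5})

    @given(
        xa=st.floats(-10, 10, allow_nan=False),
        xb=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_bounds_and_matrix_agreement(self, xa, xb):
        s = score_sample(MODEL, {"mir-a": xa, "mir-b": xb})
        assert 0.0 <= s <= MODEL.max_score
        expr = ExpressionMatrix(
            pd.DataFrame([[xa], [xb]], index=["mir-a", "mir-b"], columns=["s0"]),
            kind="normalized",
        )
        assert score_matrix(MODEL, expr)[0] == pytest.approx(s)

    def test_monotone_in_each_coordinate(self):
        g = np.random.default_rng(3)
        for _ in range(100):
            xa, xb = g.uniform(-3, 5, 2)
            s = score_sample(MODEL, {"mir-a": xa, "mir-b": xb})
            # beta_a < 0: score non-increasing in x_a
            s_up = score_sample(MODEL, {"mir-a": xa + 0.5, "mir-b": xb})
            assert s_up <= s + 1e-12
            # beta_b > 0: score non-decreasing in x_b
            s_bup = score_sample(MODEL, {"mir-a": xa, "mir-b": xb + 0.5})
            assert s_bup >= s - 1e-12

    def test_removing_entry_bounds_score_change(self):
        g = np.random.default_rng(4)
        reduced = SignatureModel([MODEL.entries[1]], cutoff=0.0)
        for _ in range(100):
            xa, xb = g.uniform(-3, 5, 2)
            full = score_sample(MODEL, {"mir-a": xa, "mir-b": xb})
            part = score_sample(reduced, {"mir-b": xb})
            assert 0 <= full - part <= abs(MODEL.entries[0].beta) + 1e-12


def _fit_inputs(seed=0, n=200):
    g = np.random.default_rng(seed)
    ids = [f"P{i}" for i in range(n)]
    x1 = g.lognormal(1.0, 0.5, n)
    x2 = g.lognormal(2.0, 0.4, n)
    risky = (x1 > np.exp(1.0)).astype(float) + (x2 < np.exp(2.0)).astype(float)
    t_ev = g.exponential(1.0 / (5e-4 * np.exp(0.9 * risky)))
    t_c = g.exponential(900.0, n)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "os_days": np.ceil(np.minimum(t_ev, t_c)) + 1,
                "os_event": (t_ev <= t_c).astype(int),
                "sample_type": "TP",
                "stage": "I",
                "age": 60,
                "sex": "male",
                "batch": "b",
                "treatment": "none",
            }
        )
    )
    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack([x1, x2]), index=["m1", "m2"], columns=ids),
        kind="normalized",
    )
    return expr, clinical


class TestFitAndApply:
    def test_median_cutoff_property(self):
        expr, clinical = _fit_inputs()
        model = fit_risk_model(expr, clinical)
        scores = score_matrix(model, expr)
        assert (scores <= model.cutoff).sum() >= np.ceil(len(scores) / 2)

    def test_refit_is_deterministic(self):
        expr, clinical = _fit_inputs()
        m1 = fit_risk_model(expr, clinical)
        m2 = fit_risk_model(expr, clinical)
        assert m1.to_dict() == m2.to_dict()

    def test_apply_to_training_reproduces_scores(self):
        expr, clinical = _fit_inputs()
        model = fit_risk_model(expr, clinical)
        assignment = apply_model(model, expr, clinical)
        assert np.allclose(assignment.score, score_matrix(model, expr))
        for s, grp in zip(assignment.score, assignment.group):
            assert grp == ("high" if s > model.cutoff else "low")

    def test_all_zero_branch_cohort_scores_zero(self):
        model = SignatureModel(
            [SignatureEntry("m1", 0.0, 0.8), SignatureEntry("m2", 100.0, -0.5)],
            cutoff=0.4,
        )
        # every sample below theta for the positive entry, above for the negative
        expr = ExpressionMatrix(
            pd.DataFrame(
                [[-1.0, -2.0], [200.0, 300.0]], index=["m1", "m2"], columns=["a", "b"]
            ),
            kind="normalized",
        )
        assignment = apply_model(model, expr)
        assert np.all(assignment.score == 0.0)
        assert assignment.group == ["low", "low"]

    def test_missing_signature_mirna_is_error(self):
        expr, clinical = _fit_inputs()
        model = fit_risk_model(expr, clinical)
        with pytest.raises(ValidationError):
            apply_model(model, expr.subset_features(["m1"]), clinical)


class TestModelSerialization:
    def test_round_trip_full_precision(self, tmp_path):
        from mirisk.io import load_model, save_model

        model = SignatureModel(
            [SignatureEntry("m", 1.2345678901234567, -0.9876543210987654)],
            cutoff=2.9000000000000004,
            expression_scale="quantile-normalized",
        )
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.to_dict() == model.to_dict()

    def test_schema_version_mismatch_rejected(self, tmp_path):
        from mirisk.io import load_model, save_model

        path = tmp_path / "model.json"
        save_model(MODEL, path)
        import json

        d = json.loads(path.read_text())
        d["schema_version"] = 99
        path.write_text(json.dumps(d))
        with pytest.raises(ValidationError, match="schema"):
            load_model(path)

    def test_truncated_json_rejected(self, tmp_path):
        from mirisk.containers import FormatError
        from mirisk.io import load_model, save_model

        path = tmp_path / "model.json"
        save_model(MODEL, path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(FormatError):
            load_model(path)
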