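"""Survival primitives: hand-computed examples, cross-checks against
lifelines / scikit-survival, and structural invariants."""
import numpy as np
import pandas as pd
import pytest

from mirisk.containers import ValidationError
from mirisk.survival import (
    KaplanMeierCurve,
    concordance,
    cox_fit,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        km = km_estimate(time, event)
        assert np.allclose(km(time), [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # events at 1, 2; censored at 1.5 among 4 subjects:
        # S(1) = 3/4, S(2) = 3/4 * (1 - 1/2) = 0.375
        km = km_estimate([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert km(1.0) == pytest.approx(0.75)
        assert km(2.0) == pytest.approx(0.375)

    def test_all_censored_curve_is_one(self):
        with pytest.warns(UserWarning):
            km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km(np.array([0.5, 2.5, 10.0])) == 1.0)

    def test_monotone_right_continuous_from_one(self, survival_cohort):
        time, event, _ = survival_cohort
        km = km_estimate(time, event)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km(0.0) == 1.0

    def test_matches_lifelines_on_random_data(self, survival_cohort):
        from lifelines import KaplanMeierFitter

        time, event, _ = survival_cohort
        km = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        grid = np.quantile(time, [0.1, 0.25, 0.5, 0.75, 0.9])
        assert np.allclose(km(grid), kmf.predict(grid).to_numpy(), atol=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        time = np.array([5.0, 8.0, 12.0, 20.0] * 2)
        event = np.array([1, 0, 1, 1] * 2)
        groups = np.array([0] * 4 + [1] * 4)
        stat, p = logrank_test(time, event, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self, survival_cohort):
        from lifelines.statistics import logrank_test as ll_logrank

        time, event, x = survival_cohort
        stat, p = logrank_test(time, event, x)
        ref = ll_logrank(time[x == 1], time[x == 0], event[x == 1], event[x == 0])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_agrees_with_permutation_reference(self):
        """The chi-square p of a 30-subject example sits within Monte-Carlo
        error of a 10,000-permutation reference."""
        g = np.random.default_rng(3)
        n = 30
        x = np.array([0] * 15 + [1] * 15)
        t_ev = g.exponential(1.0 / (0.01 * np.exp(0.9 * x)))
        t_c = g.exponential(150.0, n)
        time, event = np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int)
        stat_obs, p_chi2 = logrank_test(time, event, x)
        perm_ge = 0
        n_perm = 10000
        for _ in range(n_perm):
            xp = g.permutation(x)
            s, _ = logrank_test(time, event, xp)
            perm_ge += s >= stat_obs - 1e-12
        p_perm = perm_ge / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(p_chi2 - p_perm) < max(4 * se, 0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_direction_agrees_with_cox_sign(self, survival_cohort):
        time, event, x = survival_cohort
        fit = cox_fit(x.astype(float), time, event)
        # group 1 has higher hazard -> worse survival; beta positive
        assert fit.beta[0] > 0
        stat, p = logrank_test(time, event, x)
        assert p < 0.05 and stat > 0


class TestCox:
    def test_loglik_at_zero_beta_equals_null_loglik(self, survival_cohort):
        from mirisk.survival import _efron_loglik_grad_hess

        time, event, x = survival_cohort
        fit = cox_fit(x.astype(float), time, event)
        order = np.argsort(time, kind="stable")
        Xc = x[order, None].astype(float) - x.mean()
        ll0, _, _ = _efron_loglik_grad_hess(
            np.zeros(1), Xc, time[order], event[order], want_derivs=False
        )
        assert ll0 == pytest.approx(fit.null_loglik, abs=1e-9)
        assert fit.loglik >= fit.null_loglik - 1e-9

    def test_matches_lifelines_with_ties(self, survival_cohort):
        from lifelines import CoxPHFitter

        time, event, x = survival_cohort
        g = np.random.default_rng(2)
        X = np.column_stack([x, g.normal(size=len(x))])
        tt = np.ceil(time / 30.0)  # heavy ties
        fit = cox_fit(X, tt, event, names=["grp", "z"])
        df = pd.DataFrame(X, columns=["grp", "z"])
        df["T"], df["E"] = tt, event
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_recovers_true_beta(self):
        """Mean beta-hat within 0.05 of the true log hazard ratio 0.7."""
        g = np.random.default_rng(42)
        betas = []
        for _ in range(50):
            n = 1000
            x = g.integers(0, 2, n).astype(float)
            t_ev = g.exponential(1.0 / (1e-3 * np.exp(0.7 * x)))
            t_c = g.exponential(1500.0, n)
            time, event = np.minimum(t_ev, t_c) + 1e-9, (t_ev <= t_c).astype(int)
            betas.append(cox_fit(x, time, event).beta[0])
        assert np.mean(betas) == pytest.approx(0.7, abs=0.05)

    def test_null_covariate_coverage(self):
        """|beta| < 2 se in >= 93% of null simulations."""
        g = np.random.default_rng(5)
        cover = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 500
            x = g.normal(size=n)
            t_ev = g.exponential(500.0, n)
            t_c = g.exponential(800.0, n)
            time, event = np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int)
            fit = cox_fit(x, time, event)
            cover += abs(fit.beta[0]) < 2 * fit.se[0]
        assert cover >= 93

    def test_partial_likelihood_is_local_optimum(self, survival_cohort):
        from mirisk.survival import _efron_loglik_grad_hess

        time, event, x = survival_cohort
        g = np.random.default_rng(1)
        X = np.column_stack([x.astype(float), g.normal(size=len(x))])
        fit = cox_fit(X, time, event)
        order = np.argsort(time, kind="stable")
        Xc = X[order] - X[order].mean(axis=0)
        ll_hat, _, _ = _efron_loglik_grad_hess(fit.beta, Xc, time[order], event[order], want_derivs=False)
        for _ in range(100):
            pert = fit.beta + g.normal(scale=0.05, size=2)
            ll_p, _, _ = _efron_loglik_grad_hess(pert, Xc, time[order], event[order], want_derivs=False)
            assert ll_p <= ll_hat + 1e-10

    def test_constant_covariate_rejected(self, survival_cohort):
        time, event, _ = survival_cohort
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(np.ones_like(time), time, event)


class TestConcordance:
    def test_perfect_risk_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        score = -time  # higher score = shorter survival
        assert concordance(score, time, event) == 1.0

    def test_all_tied_scores_give_half(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance(np.zeros(4), time, np.ones(4, int)) == 0.5

    def test_random_score_near_half(self):
        g = np.random.default_rng(8)
        cs = []
        for _ in range(50):
            n = 500
            time = g.exponential(100, n)
            event = g.integers(0, 2, n)
            event[0] = 1
            cs.append(concordance(g.normal(size=n), time, event))
        assert np.mean(cs) == pytest.approx(0.5, abs=0.03)

    def test_matches_lifelines(self, survival_cohort):
        from lifelines.utils import concordance_index

        time, event, x = survival_cohort
        g = np.random.default_rng(9)
        score = x + g.normal(scale=0.5, size=len(x))
        mine = concordance(score, time, event)
        ref = 1.0 - concordance_index(time, score, event)
        assert mine == pytest.approx(ref, abs=1e-12)


class TestTimeDependentAuc:
    def test_perfect_score_no_censoring(self):
        g = np.random.default_rng(3)
        time = np.sort(g.exponential(100, 50)) + 1
        event = np.ones(50, int)
        score = -time
        auc = time_dependent_auc(score, time, event, [float(np.median(time))])
        assert auc.auc[0] == 1.0

    def test_reduces_to_empirical_auc_without_censoring(self):
        g = np.random.default_rng(12)
        n = 200
        time = g.exponential(100, n) + 1
        event = np.ones(n, int)
        score = -np.log(time) + g.normal(scale=0.5, size=n)
        t_eval = float(np.quantile(time, 0.4))
        auc = time_dependent_auc(score, time, event, [t_eval]).auc[0]
        cases, ctrl = time <= t_eval, time > t_eval
        sc, st = score[cases], score[ctrl]
        brute = float(
            ((sc[:, None] > st[None, :]) + 0.5 * (sc[:, None] == st[None, :])).mean()
        )
        assert auc == brute  # exact equality: all IPCW weights are 1

    def test_null_score_auc_near_half(self):
        g = np.random.default_rng(21)
        aucs = []
        for _ in range(50):
            n = 500
            t_ev = g.exponential(300, n)
            t_c = g.exponential(500, n)
            time, event = np.minimum(t_ev, t_c) + 1, (t_ev <= t_c).astype(int)
            aucs.append(
                time_dependent_auc(g.normal(size=n), time, event, [200.0]).auc[0]
            )
        assert np.nanmean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_matches_scikit_survival(self, survival_cohort):
        from sksurv.metrics import cumulative_dynamic_auc

        time, event, x = survival_cohort
        g = np.random.default_rng(4)
        score = x + g.normal(scale=0.7, size=len(x))
        y = np.array(
            list(zip(event.astype(bool), time)), dtype=[("e", bool), ("t", float)]
        )
        horizons = [100.0, 300.0, 600.0]
        ref, _ = cumulative_dynamic_auc(y, y, score, horizons)
        mine = time_dependent_auc(score, time, event, horizons)
        assert np.allclose(mine.auc, ref, atol=1e-10)

    def test_no_cases_yields_nan_with_warning(self):
        time = np.array([10.0, 20.0, 30.0, 40.0])
        event = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning):
            auc = time_dependent_auc(np.arange(4.0), time, event, [5.0])
        assert np.isnan(auc.auc[0])


def test_km_curve_empty_evaluates_to_one():
    km = KaplanMeierCurve(np.array([]), np.array([]))
    assert km(5.0) == 1.0 and km.left(5.0) == 1.0
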