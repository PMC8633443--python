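"""Survival-analysis primitives.

Everything downstream (the univariate screen, the permutation-importance
loop, the maximally selected cutpoint search, the greedy Cox combination
and the evaluation battery) is built on the five primitives here:

* Kaplan-Meier product-limit estimation,
* the two-group log-rank test with hypergeometric variance,
* Cox proportional-hazards fitting (Efron tie correction, damped Newton),
* Harrell's concordance index,
* cumulative/dynamic time-dependent AUC with inverse-probability-of-
  censoring weights (reverse-Kaplan-Meier, the timeROC-style estimator).

They are implemented directly (rather than wrapping a survival library)
because the cutpoint scan and the bootstrap importance loop call them
thousands of times per run and need cheap, vectorizable refits; the test
suite cross-checks them against lifelines and scikit-survival.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ValidationError


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (separation or no convergence)."""


def _as_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValidationError("time and event must be 1-d arrays of equal length")
    if (time <= 0).any():
        raise ValidationError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event indicators must be 0 or 1")
    return time, event


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit step function; S(0) = 1."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def left(self, t) -> np.ndarray:
        """Left limit S(t-)."""
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def as_table(self) -> "np.ndarray":
        return np.column_stack([self.times, self.survival])


def km_estimate(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of the survival function under right censoring.

    Censored observations reduce the risk set only. With no events the
    curve is constant 1 (with a warning).
    """
    time, event = _as_survival(time, event)
    if event.sum() == 0:
        warnings.warn("no events observed; Kaplan-Meier curve is constant 1")
        return KaplanMeierCurve(np.array([]), np.array([]))
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    # at-risk count just before each unique time; events at each unique time
    at_risk = n - first
    d = np.add.reduceat(e, first)
    keep = d > 0
    factors = 1.0 - d[keep] / at_risk[keep]
    surv = np.cumprod(factors)
    return KaplanMeierCurve(uniq[keep], surv)


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    Observed-minus-expected events in group 1 over the pooled distinct
    event times, with the hypergeometric variance; the statistic is
    chi-square with 1 df and the p-value two-sided.
    """
    stat = logrank_statistic(time, event, groups)
    return stat, float(stats.chi2.sf(stat, df=1))


def logrank_statistic(time, event, groups) -> float:
    time, event = _as_survival(time, event)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    member = (g == labels[1]).astype(float)
    if event.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    order = np.argsort(time, kind="stable")
    t, e, m = time[order], event[order], member[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    n_at_risk = n - first
    # group-1 at-risk just before each unique time (suffix sums of membership)
    suffix_m = np.concatenate([np.cumsum(m[::-1])[::-1], [0.0]])
    n1_at_risk = suffix_m[first]
    d = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * m, first)
    keep = d > 0
    nj, n1j, dj, d1j = n_at_risk[keep], n1_at_risk[keep], d[keep], d1[keep]
    expected = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    var = np.where(nj > 1, var, 0.0)
    o_minus_e = float(np.sum(d1j - expected))
    v = float(np.sum(var))
    if v <= 0:
        return 0.0
    return o_minus_e**2 / v


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards partial-likelihood fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    null_loglik: float
    lrt_p: float
    n: int
    n_events: int
    names: list[str] = field(default_factory=list)

    @property
    def lrt_stat(self) -> float:
        return 2.0 * (self.loglik - self.null_loglik)


def _efron_loglik_grad_hess(beta, X, time, event, want_derivs=True):
    """Efron-corrected partial log-likelihood and derivatives.

    Rows must be sorted by ascending time. Risk-set sums are accumulated
    from the largest time downward.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * X

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    uniq, first = np.unique(time, return_index=True)
    counts = np.diff(np.concatenate([first, [n]]))
    S = 0.0
    Z = np.zeros(p)
    Q = np.zeros((p, p))
    for j in range(len(uniq) - 1, -1, -1):
        sl = slice(first[j], first[j] + counts[j])
        S += w[sl].sum()
        Z += wX[sl].sum(axis=0)
        Q += X[sl].T @ wX[sl]
        ev = event[sl].astype(bool)
        dj = int(ev.sum())
        if dj == 0:
            continue
        Xd = X[sl][ev]
        wd = w[sl][ev]
        ll += eta[sl][ev].sum()
        Sd = wd.sum()
        Zd = (wd[:, None] * Xd).sum(axis=0)
        Qd = Xd.T @ (wd[:, None] * Xd)
        frac = np.arange(dj) / dj
        phi = S - frac * Sd  # (dj,)
        ll -= np.log(phi).sum()
        if want_derivs:
            num = Z[None, :] - frac[:, None] * Zd[None, :]  # (dj, p)
            mean = num / phi[:, None]
            grad += Xd.sum(axis=0) - mean.sum(axis=0)
            for l in range(dj):
                Ql = Q - frac[l] * Qd
                hess -= Ql / phi[l] - np.outer(mean[l], mean[l])
    return ll, grad, hess


def cox_fit(covariates, time, event, names=None, max_iter=100, tol=1e-8) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Maximizes the partial likelihood by damped Newton iterations (step
    halving when a step would decrease the likelihood) until the gradient
    norm falls below ``tol``. The likelihood-ratio p-value compares the
    fit against the null model on chi-square(p) degrees of freedom.

    Raises ConvergenceError, naming the worst covariate, on separation
    (monotone likelihood) or failure to converge.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _as_survival(time, event)
    n, p = X.shape
    if n != len(time):
        raise ValidationError("covariate rows must match survival length")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = names[int(np.argmax(sds == 0))]
        raise ValidationError(f"constant covariate: {bad}")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValidationError("Cox fit needs at least one event")
    if n_events < p:
        warnings.warn(f"fewer events ({n_events}) than covariates ({p})")

    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    # center for numerical stability; beta is unaffected
    mu = Xs.mean(axis=0)
    Xc = Xs - mu

    beta = np.zeros(p)
    null_ll, _, _ = _efron_loglik_grad_hess(beta, Xc, ts, es, want_derivs=False)
    ll, grad, hess = _efron_loglik_grad_hess(beta, Xc, ts, es)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"singular information matrix (covariate {bad})"
            ) from exc
        if np.linalg.norm(step) < 1e-12:
            # likelihood flat to machine precision; gradient is numerical noise
            converged = True
            break
        # damped Newton: halve until the likelihood does not decrease
        alpha = 1.0
        tol_ll = 1e-9 * (abs(ll) + 1.0)
        for _half in range(30):
            cand = beta + alpha * step
            cand_ll, cand_g, cand_h = _efron_loglik_grad_hess(cand, Xc, ts, es)
            if np.isfinite(cand_ll) and cand_ll >= ll - tol_ll:
                break
            alpha *= 0.5
        else:
            bad = names[int(np.argmax(np.abs(step)))]
            raise ConvergenceError(f"step halving failed (covariate {bad})")
        beta, ll, grad, hess = cand, cand_ll, cand_g, cand_h
        if np.abs(beta).max() > 50:
            bad = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood / separation suspected (covariate {bad})"
            )
    if not converged and np.linalg.norm(grad) >= tol:
        bad = names[int(np.argmax(np.abs(grad)))]
        raise ConvergenceError(f"no convergence in {max_iter} iterations ({bad})")

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("information matrix not invertible at optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    lrt = 2.0 * (ll - null_ll)
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=p))
    return CoxFit(
        beta=beta,
        se=se,
        loglik=float(ll),
        null_loglik=float(null_ll),
        lrt_p=lrt_p,
        n=n,
        n_events=n_events,
        names=list(names),
    )


def concordance(score, time, event) -> float:
    """Harrell's c-index over usable pairs.

    A pair is usable when the shorter observed time carries an event;
    higher score is taken to mean higher risk (shorter survival). Score
    ties count 1/2.
    """
    s = np.asarray(score, dtype=float)
    time, event = _as_survival(time, event)
    # usable (i, j): t_i < t_j and e_i = 1
    ti = time[:, None]
    usable = (ti < time[None, :]) & (event[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValidationError("no usable pairs for concordance")
    si = s[:, None]
    concordant = (si > s[None, :]) & usable
    tied = (si == s[None, :]) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


@dataclass
class AucCurve:
    """Time-dependent AUC evaluated at fixed horizons (days)."""

    eval_times: list[float]
    auc: list[float]

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.eval_times, self.auc))


def censoring_km(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of the censoring distribution (reverse KM)."""
    time, event = _as_survival(time, event)
    with warnings.catch_warnings():
        # an uncensored cohort legitimately yields the constant-1 curve
        warnings.simplefilter("ignore")
        return km_estimate(time, 1 - event)


def time_dependent_auc(score, time, event, eval_times) -> AucCurve:
    """Cumulative-case / dynamic-control AUC with IPCW.

    Cases at horizon t are subjects with an observed event by t, weighted
    by 1/G(T_i-); controls are subjects still under observation past t,
    weighted by 1/G(t), where G is the reverse-Kaplan-Meier estimate of
    the censoring survival function. With no censoring every weight is 1
    and the estimator reduces to the empirical AUC of cases vs survivors.
    Horizons with no cases or no controls yield NaN with a warning.
    """
    s = np.asarray(score, dtype=float)
    time, event = _as_survival(time, event)
    if len(s) != len(time):
        raise ValidationError("score length must match survival length")
    max_t = time.max()
    G = censoring_km(time, event)
    aucs = []
    for t in eval_times:
        if t >= max_t:
            warnings.warn(f"evaluation time {t} is beyond the largest observed time")
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            warnings.warn(f"no cases or no controls at t={t}; AUC undefined")
            aucs.append(float("nan"))
            continue
        g_case = np.asarray(G.left(time[cases]))
        g_ctrl = float(G(t))
        if g_ctrl <= 0 or (g_case <= 0).any():
            warnings.warn(f"zero censoring-survival weight at t={t}; AUC undefined")
            aucs.append(float("nan"))
            continue
        w_case = 1.0 / g_case
        w_ctrl = np.full(int(controls.sum()), 1.0 / g_ctrl)
        sc, st = s[cases], s[controls]
        gt = (sc[:, None] > st[None, :]).astype(float)
        gt += 0.5 * (sc[:, None] == st[None, :])
        W = np.outer(w_case, w_ctrl)
        aucs.append(float((W * gt).sum() / W.sum()))
    return AucCurve(eval_times=list(map(float, eval_times)), auc=aucs)
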