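"""The threshold/beta risk-score estimator.

For each signature miRNA an optimal expression cutpoint theta_i is found
by maximally selected log-rank statistics (exhaustive scan over
admissible cutpoints), and a coefficient beta_i is the univariate Cox
log hazard ratio of the indicator 1[x > theta_i]. A patient's score sums
per-miRNA contributions

    s_i = |beta_i|  if beta_i < 0 and x_i < theta_i        (low expression risky)
    s_i =  beta_i   if beta_i > 0 and x_i > theta_i        (high expression risky)
    s_i =  0        otherwise,

with strict inequalities, so a value sitting exactly at its threshold
contributes nothing. The cohort is dichotomized at the training-median
score; validation cohorts reuse that fixed cutoff, never a recomputed
one. Because each contribution is a |beta|, the score lives in
[0, sum_i |beta_i|] regardless of the expression scale, which is what
lets signatures from different data types be combined additively.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, ValidationError
from .survival import cox_fit, logrank_statistic

MODEL_SCHEMA_VERSION = 1


@dataclass
class SignatureEntry:
    mirna_id: str
    theta: float
    beta: float


@dataclass
class SignatureModel:
    """Fitted signature: ordered (miRNA, threshold, coefficient) + score cutoff."""

    entries: list[SignatureEntry]
    cutoff: float
    expression_scale: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("signature model needs at least one entry")
        ids = [e.mirna_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate miRNA ids in signature model")
        if not all(np.isfinite(e.theta) and np.isfinite(e.beta) for e in self.entries):
            raise ValidationError("non-finite threshold or coefficient")
        if not np.isfinite(self.cutoff):
            raise ValidationError("non-finite score cutoff")

    @property
    def mirna_ids(self) -> list[str]:
        return [e.mirna_id for e in self.entries]

    @property
    def max_score(self) -> float:
        return float(sum(abs(e.beta) for e in self.entries))

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "entries": [
                {"mirna_id": e.mirna_id, "theta": e.theta, "beta": e.beta}
                for e in self.entries
            ],
            "cutoff": self.cutoff,
            "expression_scale": self.expression_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        version = d.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValidationError(
                f"model schema version mismatch: file has {version!r}, "
                f"expected {MODEL_SCHEMA_VERSION}"
            )
        entries = [
            SignatureEntry(str(e["mirna_id"]), float(e["theta"]), float(e["beta"]))
            for e in d["entries"]
        ]
        return cls(
            entries=entries,
            cutoff=float(d["cutoff"]),
            expression_scale=str(d.get("expression_scale", "unspecified")),
        )


@dataclass
class RiskAssignment:
    """Per-sample risk score and high/low group (score > cutoff -> high)."""

    sample_ids: list[str]
    score: np.ndarray
    group: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score, "group": self.group}
        )


def candidate_cutpoints(x: np.ndarray, min_group_frac: float) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, restricted so
    each side of the split holds at least ``min_group_frac`` of samples."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    uniq = np.unique(x)
    if len(uniq) < 2:
        return np.array([])
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    min_n = min_group_frac * n
    n_low = np.searchsorted(np.sort(x), mids, side="right")
    ok = (n_low >= min_n) & ((n - n_low) >= min_n)
    return mids[ok]


def optimal_threshold(
    x, time, event, min_group_frac: float = 0.1
) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint.

    Scans every admissible cutpoint (midpoints between consecutive
    distinct values, both sides holding >= min_group_frac of the cohort)
    and returns the one maximizing the two-group log-rank statistic,
    breaking exact ties toward the cutpoint nearest the median
    expression. Returns (theta, logrank_statistic).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValidationError("optimal_threshold needs at least 10 samples")
    cuts = candidate_cutpoints(x, min_group_frac)
    if len(cuts) == 0:
        raise ValidationError(
            f"no cutpoint satisfies min_group_frac={min_group_frac}"
        )
    stats_ = np.array(
        [logrank_statistic(time, event, (x > c).astype(int)) for c in cuts]
    )
    best = stats_.max()
    tied = np.nonzero(stats_ >= best - 1e-12)[0]
    med = np.median(x)
    theta = cuts[tied[np.argmin(np.abs(cuts[tied] - med))]]
    return float(theta), float(best)


def beta_at_threshold(x, theta: float, time, event) -> float:
    """Univariate Cox coefficient of the indicator 1[x > theta].

    beta > 0 means high expression is hazardous; beta < 0 protective
    (equivalently: low expression hazardous).
    """
    x = np.asarray(x, dtype=float)
    ind = (x > theta).astype(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ValidationError(f"threshold {theta} leaves one side empty")
    fit = cox_fit(ind, time, event, names=["above_threshold"])
    return float(fit.beta[0])


def score_sample(model: SignatureModel, x: dict[str, float] | pd.Series) -> float:
    """Evaluate the piecewise risk score for one sample.

    ``x`` maps each signature miRNA to its expression on the model's
    recorded scale. Missing or non-finite values raise.
    """
    total = 0.0
    for e in model.entries:
        if e.mirna_id not in x:
            raise ValidationError(f"missing expression for signature miRNA {e.mirna_id}")
        xi = float(x[e.mirna_id])
        if not np.isfinite(xi):
            raise ValidationError(f"non-finite expression for {e.mirna_id}")
        if e.beta < 0 and xi < e.theta:
            total += abs(e.beta)
        elif e.beta > 0 and xi > e.theta:
            total += e.beta
    return total


def score_matrix(model: SignatureModel, expr: ExpressionMatrix) -> np.ndarray:
    """Vectorized risk scores for every sample column of ``expr``."""
    missing = [m for m in model.mirna_ids if m not in expr.values.index]
    if missing:
        raise ValidationError(f"expression matrix lacks signature miRNAs: {missing}")
    X = expr.values.loc[model.mirna_ids].to_numpy(dtype=float)  # (k, n)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite expression among signature miRNAs")
    thetas = np.array([e.theta for e in model.entries])[:, None]
    betas = np.array([e.beta for e in model.entries])[:, None]
    contrib = np.where(
        (betas < 0) & (X < thetas),
        np.abs(betas),
        np.where((betas > 0) & (X > thetas), betas, 0.0),
    )
    return contrib.sum(axis=0)


def fit_risk_model(
    signature_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    min_group_frac: float = 0.1,
    expression_scale: str = "unspecified",
) -> SignatureModel:
    """Fit thresholds and coefficients for every signature miRNA, then set
    the cohort cutoff at the median training score."""
    time, event, ids = clinical.survival_arrays()
    expr = signature_expr.subset_samples(ids)
    entries = []
    for mid in expr.feature_ids:
        x = expr.values.loc[mid].to_numpy(dtype=float)
        try:
            theta, _ = optimal_threshold(x, time, event, min_group_frac)
            beta = beta_at_threshold(x, theta, time, event)
        except (ValidationError, RuntimeError) as exc:
            raise ValidationError(f"fitting signature miRNA {mid} failed: {exc}") from exc
        entries.append(SignatureEntry(mid, theta, beta))
    model = SignatureModel(entries=entries, cutoff=0.0, expression_scale=expression_scale)
    scores = score_matrix(model, expr)
    model.cutoff = float(np.median(scores))
    return model


def apply_model(
    model: SignatureModel, expr: ExpressionMatrix, clinical: ClinicalTable | None = None
) -> RiskAssignment:
    """Score a cohort and assign groups with the FIXED training cutoff.

    Ties at the cutoff go to the low-risk group. The cutoff is never
    recomputed on the new cohort.
    """
    if clinical is not None:
        keep = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
        expr = expr.subset_samples(keep)
    scores = score_matrix(model, expr)
    groups = ["high" if s > model.cutoff else "low" for s in scores]
    return RiskAssignment(sample_ids=expr.sample_ids, score=scores, group=groups)
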