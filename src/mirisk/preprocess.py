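"""Sample/feature filtering, quantile normalization and batch harmonization.

The canonical order of operations is: sample filter (tumor/normal
selection plus minimum follow-up), zero-fraction feature filter,
quantile normalization, then batch adjustment when more than one cohort
is present. ``preprocess_expression`` applies that order and reports the
counts removed at each step.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def filter_zero_features(X: ExpressionMatrix, max_zero_frac: float) -> ExpressionMatrix:
    """Drop features whose zero fraction exceeds ``max_zero_frac``.

    A feature with zeros in *more than* the given fraction of samples is
    removed (at exactly the threshold it is kept). Feature order and the
    sample set are preserved.
    """
    if not (0.0 <= max_zero_frac <= 1.0):
        raise ValidationError("max_zero_frac must lie in [0, 1]")
    zero_frac = (X.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        raise ValidationError(
            f"no features survive the zero filter at max_zero_frac={max_zero_frac}"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("zero filter removed %d/%d features", n_drop, X.n_features)
    return ExpressionMatrix(X.values.loc[keep], kind=X.kind)


def quantile_normalize(X: ExpressionMatrix, log_transform_counts: bool = True) -> ExpressionMatrix:
    """Force every sample column onto the common rank-mean distribution.

    The reference distribution is the across-sample mean of the sorted
    columns; each column's values are replaced by the reference value of
    their within-column rank, with ties receiving the mean of their
    ranks' reference values. Counts are first transformed log2(x+1) (the
    output is flagged normalized).
    """
    vals = X.values.to_numpy(dtype=float)
    if X.kind == "counts":
        if not log_transform_counts:
            raise ValidationError(
                "quantile_normalize needs continuous values; pass "
                "log_transform_counts=True to apply log2(x+1) first"
            )
        vals = np.log2(vals + 1.0)
    n_feat, n_samp = vals.shape
    if n_samp < 2:
        warnings.warn("single-sample input: quantile normalization is the identity")
        return ExpressionMatrix(
            pd.DataFrame(vals, index=X.values.index, columns=X.values.columns),
            kind="normalized",
        )
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samp):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        srt = col[order]
        # tied values share the mean of the reference values at their ranks
        starts = np.concatenate([[0], np.nonzero(np.diff(srt))[0] + 1])
        sizes = np.diff(np.concatenate([starts, [n_feat]]))
        group_means = np.add.reduceat(reference, starts) / sizes
        out[order, j] = np.repeat(group_means, sizes)
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.values.index, columns=X.values.columns),
        kind="normalized",
    )


def filter_samples(
    clinical: ClinicalTable,
    min_os_days: float = 30.0,
    keep_types: tuple[str, ...] = ("TP", "NT"),
) -> ClinicalTable:
    """Restrict sample types and enforce a minimum follow-up on tumor samples.

    Tumor (TP) samples with overall survival below ``min_os_days`` are
    excluded to avoid deaths from unrelated causes; normal-tissue samples
    are exempt (they typically carry no survival at all).
    """
    df = clinical.data
    df = df[df["sample_type"].isin(keep_types)]
    days = pd.to_numeric(df["os_days"], errors="coerce")
    short = (df["sample_type"] == "TP") & days.notna() & (days < min_os_days)
    # TP samples with entirely missing follow-up cannot enter survival analysis
    no_fu = (df["sample_type"] == "TP") & days.isna()
    out = df[~(short | no_fu)].copy()
    if (out["sample_type"] == "TP").sum() == 0 and "TP" in keep_types:
        raise ValidationError(
            f"no tumor samples remain after the {min_os_days}-day follow-up filter"
        )
    n_drop = len(df) - len(out)
    if n_drop:
        log.info("sample filter removed %d samples", n_drop)
    return ClinicalTable(out)


def batch_adjust(
    X: ExpressionMatrix,
    batch_labels,
    reference_batch: str | None = None,
) -> ExpressionMatrix:
    """Per-feature location-scale batch harmonization.

    Each batch's values are standardized per feature and rescaled to the
    pooled per-feature mean and standard deviation, so per-feature batch
    means agree after adjustment. With ``reference_batch`` the target
    moments are that batch's instead of the pooled ones (and the
    reference batch itself is left untouched) — the mode used when a
    validation cohort must be expressed on an already-fitted training
    scale. Features with zero variance within a batch are mean-shifted
    only.
    """
    labels = np.asarray(batch_labels)
    if len(labels) != X.n_samples:
        raise ValidationError("batch labels must match the sample count")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        warnings.warn("single batch: batch adjustment is the identity")
        return ExpressionMatrix(X.values.copy(), kind=X.kind)
    if (counts < 3).any():
        small = uniq[counts < 3].tolist()
        raise ValidationError(f"batches need >= 3 samples each; too small: {small}")
    if reference_batch is not None and reference_batch not in uniq:
        raise ValidationError(f"reference batch {reference_batch!r} not present")

    vals = X.values.to_numpy(dtype=float)
    if reference_batch is None:
        target_mean = vals.mean(axis=1)
        target_sd = vals.std(axis=1, ddof=1)
    else:
        ref = vals[:, labels == reference_batch]
        target_mean = ref.mean(axis=1)
        target_sd = ref.std(axis=1, ddof=1)

    out = np.empty_like(vals)
    n_zero_var = 0
    for b in uniq:
        mask = labels == b
        if reference_batch is not None and b == reference_batch:
            out[:, mask] = vals[:, mask]
            continue
        block = vals[:, mask]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        n_zero_var += int(zero.sum())
        scale = np.where(zero, 1.0, target_sd / np.where(zero, 1.0, sd))
        out[:, mask] = (block - mu[:, None]) * scale[:, None] + target_mean[:, None]
    if n_zero_var:
        log.info("%d feature/batch cells had zero variance; mean-shifted only", n_zero_var)
    if reference_batch is None:
        # restore the pooled per-feature moments exactly (batch means stay equal
        # under a common affine map)
        mu_new = out.mean(axis=1)
        sd_new = out.std(axis=1, ddof=1)
        ok = sd_new > 0
        scale = np.where(ok, target_sd / np.where(ok, sd_new, 1.0), 1.0)
        out = (out - mu_new[:, None]) * scale[:, None] + target_mean[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.values.index, columns=X.values.columns),
        kind="normalized",
    )


def preprocess_expression(
    X: ExpressionMatrix,
    clinical: ClinicalTable,
    min_os_days: float = 30.0,
    max_zero_frac: float = 0.9,
    keep_types: tuple[str, ...] = ("TP", "NT"),
    quantile: bool = True,
) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Full preprocessing chain; returns (expression, clinical, report)."""
    report: dict = {"n_samples_in": clinical.n_samples, "n_features_in": X.n_features}
    clin = filter_samples(clinical, min_os_days=min_os_days, keep_types=keep_types)
    shared = [s for s in X.sample_ids if s in set(clin.sample_ids)]
    clin = clin.subset(shared)
    Xf = X.subset_samples(shared)
    report["n_samples_kept"] = len(shared)
    Xf = filter_zero_features(Xf, max_zero_frac)
    report["n_features_kept"] = Xf.n_features
    if quantile:
        Xf = quantile_normalize(Xf)
        report["quantile_normalized"] = True
        report["scale"] = "log2(x+1), quantile-normalized" if X.kind == "counts" else "quantile-normalized"
    else:
        report["quantile_normalized"] = False
        report["scale"] = "as-input"
    return Xf, clin, report
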