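"""Signature selection: univariate screen, permutation-importance rank
matrix, importance clustering, and greedy multivariate combination.

The four stages mirror a robust feature-selection recipe for survival
signatures:

1. keep candidates whose median-dichotomized expression separates
   survival (log-rank; raw p by default, optionally BH-corrected);
2. repeat B times: bootstrap the cohort, fit a multivariate Cox model on
   the in-bag samples (median-dichotomized indicators), and measure each
   candidate's permutation importance as the out-of-bag concordance drop
   when its column is shuffled; rank candidates within each repeat;
3. cluster the m x B rank rows (complete-linkage, Euclidean) into k
   groups, drop the group with the worst median rank ("meaningless"),
   and order survivors by median rank;
4. feed survivors in order into a Cox model, keeping each only if the
   model's prognostic ability, -log10 of the likelihood-ratio p-value,
   strictly improves.

The importance engine is bootstrap-plus-OOB permutation around the Cox
model — the same "shuffle a variable, measure the performance drop"
principle a random survival forest uses, but with a single transparent
model per repeat.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ExpressionMatrix, ValidationError
from .screen import bh_adjust
from .survival import ConvergenceError, concordance, cox_fit, logrank_test

log = logging.getLogger(__name__)


def _median_indicator(x: np.ndarray) -> np.ndarray:
    """1[x > median(x)]; raises if the split leaves a side empty."""
    med = np.median(x)
    ind = (x > med).astype(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ValidationError("median split leaves an empty group")
    return ind


def univariate_screen(
    candidate_expr: ExpressionMatrix,
    time,
    event,
    screen_p: float = 0.05,
    adjust: str = "none",
) -> list[str]:
    """Log-rank screen of median-dichotomized candidates.

    Retains candidates with log-rank p (raw by default, BH-adjusted with
    ``adjust="BH"``) below ``screen_p``. Candidates whose median split
    degenerates (>= 50% ties at the median) are dropped with a log entry
    rather than failing the screen.
    """
    ids, ps = [], []
    for mid in candidate_expr.feature_ids:
        x = candidate_expr.values.loc[mid].to_numpy(dtype=float)
        try:
            ind = _median_indicator(x)
        except ValidationError:
            log.info("candidate %s dropped: degenerate median split", mid)
            continue
        _, p = logrank_test(time, event, ind.astype(int))
        ids.append(mid)
        ps.append(p)
    if not ids:
        return []
    if adjust == "BH":
        ps = bh_adjust(ps)
    elif adjust != "none":
        raise ValidationError(f"unknown screen adjustment: {adjust!r}")
    return [mid for mid, p in zip(ids, ps) if p < screen_p]


@dataclass
class RankMatrix:
    """Candidate x repeat importance ranks; every column permutes 1..m."""

    mirna_ids: list[str]
    ranks: np.ndarray  # (m, B) integers

    def __post_init__(self) -> None:
        m, B = self.ranks.shape
        if m != len(self.mirna_ids):
            raise ValidationError("rank matrix shape does not match ids")
        expected = np.arange(1, m + 1)
        for b in range(B):
            if not np.array_equal(np.sort(self.ranks[:, b]), expected):
                raise ValidationError(f"column {b} is not a permutation of 1..{m}")

    @property
    def n_repeats(self) -> int:
        return self.ranks.shape[1]

    def median_rank(self) -> pd.Series:
        return pd.Series(np.median(self.ranks, axis=1), index=self.mirna_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranks,
            index=self.mirna_ids,
            columns=[f"rep_{b}" for b in range(self.ranks.shape[1])],
        )


def _rank_drops(drops: np.ndarray, ids: list[str]) -> np.ndarray:
    """Ranks 1..m, largest concordance drop first; ties broken by id."""
    id_order = np.argsort(np.argsort(ids))
    order = np.lexsort((id_order, -drops))
    ranks = np.empty(len(drops), dtype=int)
    ranks[order] = np.arange(1, len(drops) + 1)
    return ranks


def importance_rank_matrix(
    screened_expr: ExpressionMatrix,
    time,
    event,
    B: int = 5000,
    seed: int = 0,
) -> RankMatrix:
    """Bootstrap + out-of-bag permutation importance, repeated B times.

    Per repeat: draw a bootstrap sample, fit the multivariate Cox model
    on the in-bag data (median-dichotomized indicators, medians from the
    full cohort), score the out-of-bag samples, then shuffle each
    candidate's OOB column in turn and record the concordance drop.
    Repeats whose model fails to fit (e.g. separation in a small
    bootstrap) are redrawn, up to 3B attempts.
    """
    ids = screened_expr.feature_ids
    m = len(ids)
    if m < 2:
        raise ValidationError("importance needs >= 2 screened candidates")
    if B < 1:
        raise ValidationError("B must be >= 1")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    X = np.stack(
        [
            _median_indicator(screened_expr.values.loc[mid].to_numpy(dtype=float))
            for mid in ids
        ],
        axis=1,
    )  # (n, m)
    rng = np.random.default_rng(seed)
    ranks = np.empty((m, B), dtype=int)
    attempts = 0
    b = 0
    while b < B:
        attempts += 1
        if attempts > 3 * B:
            raise ConvergenceError(
                f"too many failed bootstrap repeats ({attempts - 1} attempts for {b} successes)"
            )
        in_bag = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(in_bag)] = False
        if oob_mask.sum() < 10 or event[oob_mask].sum() < 2:
            continue
        try:
            fit = cox_fit(X[in_bag], time[in_bag], event[in_bag], names=ids)
        except (ConvergenceError, ValidationError):
            log.debug("bootstrap repeat failed to fit; redrawing")
            continue
        Xo = X[oob_mask]
        to, eo = time[oob_mask], event[oob_mask]
        try:
            c_full = concordance(Xo @ fit.beta, to, eo)
        except ValidationError:
            continue
        drops = np.empty(m)
        for j in range(m):
            perm = rng.permutation(Xo.shape[0])
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            drops[j] = c_full - concordance(Xp @ fit.beta, to, eo)
        ranks[:, b] = _rank_drops(drops, ids)
        b += 1
    return RankMatrix(mirna_ids=list(ids), ranks=ranks)


def cluster_importance(
    rank_matrix: RankMatrix, k: int = 3
) -> tuple[pd.Series, list[str]]:
    """Cluster candidates by their rank profiles and drop the worst group.

    Complete-linkage agglomerative clustering (Euclidean distance on the
    rank rows) cut at k groups; groups are ordered by within-group
    median rank and the worst ("meaningless") group is discarded.
    Returns (group label per miRNA, survivors ordered by median rank
    ascending, ties by id).
    """
    m = len(rank_matrix.mirna_ids)
    if k > m:
        raise ValidationError(f"k={k} exceeds the number of candidates ({m})")
    Z = linkage(rank_matrix.ranks.astype(float), method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    groups = pd.Series(labels, index=rank_matrix.mirna_ids, name="group")
    group_median = {
        g: float(np.median(rank_matrix.ranks[labels == g])) for g in np.unique(labels)
    }
    worst = max(group_median, key=group_median.get)
    med = rank_matrix.median_rank()
    survivors = [mid for mid in rank_matrix.mirna_ids if groups[mid] != worst]
    survivors.sort(key=lambda mid: (med[mid], mid))
    return groups, survivors


@dataclass
class SelectionTrace:
    """Record of every greedy attempt: candidate, score achieved, kept?"""

    ordered_candidates: list[str] = field(default_factory=list)
    step_scores: list[float] = field(default_factory=list)
    included: list[bool] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": self.ordered_candidates,
                "neg_log10_lrt_p": self.step_scores,
                "included": self.included,
            }
        )


def greedy_select(
    ordered_candidates: list[str],
    expr: ExpressionMatrix,
    time,
    event,
) -> tuple[list[str], SelectionTrace]:
    """Greedy forward combination under the -log10 LRT-p criterion.

    Candidates are attempted in the given order as median-dichotomized
    indicators in a multivariate Cox model; one is kept only if the
    model's -log10(likelihood-ratio p) strictly increases over the
    current kept set. Candidates that break the fit (collinearity,
    separation) are rejected. The first candidate must fit.
    """
    if not ordered_candidates:
        raise ValidationError("no candidates to select from")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    trace = SelectionTrace()
    kept: list[str] = []
    kept_X: list[np.ndarray] = []
    best_score = -np.inf
    for mid in ordered_candidates:
        x = expr.values.loc[mid].to_numpy(dtype=float)
        try:
            ind = _median_indicator(x)
        except ValidationError:
            trace.ordered_candidates.append(mid)
            trace.step_scores.append(best_score if kept else float("nan"))
            trace.included.append(False)
            continue
        X = np.stack(kept_X + [ind], axis=1)
        try:
            fit = cox_fit(X, time, event, names=kept + [mid])
            score = float(-np.log10(max(fit.lrt_p, 1e-300)))
        except (ConvergenceError, ValidationError) as exc:
            if not kept:
                raise ValidationError(
                    f"first candidate {mid} failed to fit: {exc}"
                ) from exc
            score = -np.inf
        keep = score > best_score
        trace.ordered_candidates.append(mid)
        trace.step_scores.append(score)
        trace.included.append(bool(keep))
        if keep:
            kept.append(mid)
            kept_X.append(ind)
            best_score = score
    return kept, trace
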