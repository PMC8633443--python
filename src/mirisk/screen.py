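"""Candidate screening: differential expression, negative-regulation
pairs, and over-representation analysis.

The miRNA universe is reduced to miRNAs with experimental target
support whose target gene (i) is differentially expressed between tumor
and normal tissue, (ii) is negatively correlated with the miRNA across
tumor samples (Spearman, BH-adjusted), and (iii) belongs to at least one
functionally enriched gene set. Differential expression is a
median-of-ratios-normalized Welch's t on log2 counts — a deliberately
light-weight stand-in for a negative-binomial GLM that preserves the
stage's contract: a calibrated, ranked DE gene list under the published
adjusted-p and fold-change thresholds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidatedPair,
    ValidationError,
)

log = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    gene_id: str
    log2fc: float  # tumor over normal
    p: float
    adj_p: float
    direction: str  # up | down
    significant: bool


def size_factors(counts: ExpressionMatrix) -> np.ndarray:
    """DESeq-style median-of-ratios size factors, normalized to geometric
    mean 1. Only genes with all-positive counts enter the reference."""
    if counts.kind != "counts":
        raise ValidationError("size factors are defined for counts matrices")
    mat = counts.values.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference fallback (add a pseudocount)"
        )
    sub = mat[positive]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.log(sf).mean())
    return sf


def differential_expression(
    counts: ExpressionMatrix,
    group_labels,
    cfg: PipelineConfig | None = None,
) -> list[DEResult]:
    """Tumor-vs-normal differential expression on raw counts.

    Counts are scaled by median-of-ratios size factors; the log2 fold
    change compares group means of normalized counts with pseudo-count
    0.5, and the p-value is a two-sided Welch's t on log2(normalized +
    0.5). Significance requires BH-adjusted p below ``cfg.de_adj_p`` AND
    |log2FC| >= ``cfg.de_abs_log2fc``.
    """
    cfg = cfg or PipelineConfig()
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if not set(groups) <= {"TP", "NT"}:
        raise ValidationError(f"group labels must be TP/NT, got {list(groups)}")
    tp, nt = labels == "TP", labels == "NT"
    if tp.sum() < 2 or nt.sum() < 2:
        raise ValidationError("each group needs >= 2 samples for a variance estimate")
    sf = size_factors(counts)
    norm = counts.values.to_numpy(dtype=float) / sf[None, :]
    logn = np.log2(norm + 0.5)
    mean_tp = norm[:, tp].mean(axis=1)
    mean_nt = norm[:, nt].mean(axis=1)
    log2fc = np.log2(mean_tp + 0.5) - np.log2(mean_nt + 0.5)
    tstat, p = stats.ttest_ind(logn[:, tp], logn[:, nt], axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes are uninformative
    adj = bh_adjust(p)
    out = []
    for i, gid in enumerate(counts.feature_ids):
        sig = bool(adj[i] < cfg.de_adj_p and abs(log2fc[i]) >= cfg.de_abs_log2fc)
        out.append(
            DEResult(
                gene_id=gid,
                log2fc=float(log2fc[i]),
                p=float(p[i]),
                adj_p=float(adj[i]),
                direction="up" if log2fc[i] >= 0 else "down",
                significant=sig,
            )
        )
    return out


def de_gene_ids(results: list[DEResult]) -> list[str]:
    return [r.gene_id for r in results if r.significant]


@dataclass
class EnrichedTerm:
    set_name: str
    overlap: int
    set_size: int
    universe_size: int
    n_selected: int
    p: float
    adj_p: float
    enriched: bool


def ora_enrichment(
    selected_genes,
    universe,
    gene_sets: GeneSetCollection,
    cfg: PipelineConfig | None = None,
) -> list[EnrichedTerm]:
    """Hypergeometric over-representation of ``selected_genes`` in each set.

    Sets are intersected with the universe first; the upper-tail
    hypergeometric p (P[overlap >= observed]) is BH-corrected across
    sets.
    """
    cfg = cfg or PipelineConfig()
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe for enrichment")
    selected = set(selected_genes)
    if not selected <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    N, n_sel = len(universe), len(selected)
    restricted = gene_sets.restrict_to(universe)
    names, ps, overlaps, sizes = [], [], [], []
    for name, members in restricted.sets.items():
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        # P[X >= k] for X ~ Hypergeom(N, K, n_sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        names.append(name)
        ps.append(min(p, 1.0))
        overlaps.append(k)
        sizes.append(K)
    adj = bh_adjust(ps) if ps else np.array([])
    return [
        EnrichedTerm(
            set_name=names[i],
            overlap=overlaps[i],
            set_size=sizes[i],
            universe_size=N,
            n_selected=n_sel,
            p=ps[i],
            adj_p=float(adj[i]),
            enriched=bool(adj[i] < cfg.ora_adj_p),
        )
        for i in range(len(names))
    ]


@dataclass
class RegulationPair:
    mirna_id: str
    gene_id: str
    rho: float
    p: float
    adj_p: float


def negative_pairs(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    validated: list[ValidatedPair],
    de_genes,
    cfg: PipelineConfig | None = None,
) -> list[RegulationPair]:
    """Spearman-filtered negative regulation pairs.

    Each validated pair whose gene is differentially expressed is tested
    for monotone association across the shared samples; pairs with
    negative rho and BH-adjusted p below ``cfg.pair_adj_p`` are retained.
    Pairs with constant expression in either feature are dropped with a
    log entry.
    """
    cfg = cfg or PipelineConfig()
    shared = [s for s in mirna_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(shared) < 10:
        raise ValidationError(f"need >= 10 shared samples, got {len(shared)}")
    de_set = set(de_genes)
    testable = [
        p
        for p in validated
        if p.gene_id in de_set
        and p.mirna_id in mirna_expr.values.index
        and p.gene_id in gene_expr.values.index
    ]
    if not testable:
        return []
    M = mirna_expr.values.loc[:, shared]
    G = gene_expr.values.loc[:, shared]
    tested: list[tuple[ValidatedPair, float, float]] = []
    n_const = 0
    for pair in testable:
        x = M.loc[pair.mirna_id].to_numpy(dtype=float)
        y = G.loc[pair.gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_const += 1
            continue
        rho, p = stats.spearmanr(x, y)
        tested.append((pair, float(rho), float(p)))
    if n_const:
        log.info("dropped %d pairs with constant expression", n_const)
    if not tested:
        return []
    adj = bh_adjust([t[2] for t in tested])
    out = []
    for (pair, rho, p), ap in zip(tested, adj):
        if rho < 0 and ap < cfg.pair_adj_p:
            out.append(RegulationPair(pair.mirna_id, pair.gene_id, rho, p, float(ap)))
    return out


def restrict_candidates(
    pairs: list[RegulationPair],
    enriched_terms: list[EnrichedTerm],
    gene_sets: GeneSetCollection,
) -> list[str]:
    """miRNAs with at least one retained pair whose gene belongs to at
    least one enriched set; deduplicated, lexicographic order."""
    enriched_names = [t.set_name for t in enriched_terms if t.enriched]
    if not enriched_names:
        raise ValidationError("no enriched gene sets; candidate set would be empty")
    enriched_genes: set[str] = set()
    for name in enriched_names:
        enriched_genes |= set(gene_sets.sets.get(name, frozenset()))
    candidates = sorted({p.mirna_id for p in pairs if p.gene_id in enriched_genes})
    if not candidates:
        raise ValidationError("no candidate miRNAs survive the functional restriction")
    return candidates
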