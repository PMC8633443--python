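"""End-to-end orchestration: from matrices to a fitted, evaluated model.

`run_discovery` chains preprocessing, candidate screening, signature
selection and risk-model fitting on a training cohort; `apply_external`
harmonizes an external cohort onto the training expression scale and
scores it with the fixed training cutoff.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ValidatedPair,
    ValidationError,
)
from .evaluate import EvaluationReport, evaluate_cohort
from .preprocess import batch_adjust, filter_samples, preprocess_expression
from .risk import RiskAssignment, SignatureModel, apply_model, fit_risk_model
from .screen import (
    DEResult,
    EnrichedTerm,
    RegulationPair,
    de_gene_ids,
    differential_expression,
    negative_pairs,
    ora_enrichment,
    restrict_candidates,
)
from .select import (
    RankMatrix,
    SelectionTrace,
    cluster_importance,
    greedy_select,
    importance_rank_matrix,
    univariate_screen,
)

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass
class DiscoveryResult:
    """Everything the discovery run produced, stage by stage."""

    de_results: list[DEResult]
    enriched_terms: list[EnrichedTerm]
    retained_pairs: list[RegulationPair]
    candidates: list[str]
    screened: list[str]
    rank_matrix: RankMatrix | None
    importance_groups: pd.Series | None
    ordered_survivors: list[str]
    signature: list[str]
    trace: SelectionTrace
    model: SignatureModel
    mirna_expr: ExpressionMatrix  # preprocessed, tumor samples
    clinical: ClinicalTable  # filtered, tumor samples
    training_assignment: RiskAssignment
    training_report: EvaluationReport
    preprocess_report: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_de_genes": sum(r.significant for r in self.de_results),
            "n_enriched_terms": sum(t.enriched for t in self.enriched_terms),
            "n_retained_pairs": len(self.retained_pairs),
            "n_candidates": len(self.candidates),
            "n_screened": len(self.screened),
            "n_survivors": len(self.ordered_survivors),
            "signature": self.signature,
            "cutoff": self.model.cutoff,
            "overall_logrank_p": self.training_report.overall_logrank_p,
            "auc_by_time": self.training_report.auc_by_time.as_dict(),
        }


def run_discovery(
    mirna: ExpressionMatrix,
    gene_counts: ExpressionMatrix,
    clinical: ClinicalTable,
    validated_pairs: list[ValidatedPair],
    gene_sets: GeneSetCollection,
    cfg: PipelineConfig | None = None,
) -> DiscoveryResult:
    """Run the complete discovery pipeline on a training cohort."""
    cfg = cfg or PipelineConfig()

    # --- preprocessing -----------------------------------------------------
    clin = filter_samples(clinical, min_os_days=cfg.min_os_days)
    mirna_pp, clin_m, pp_report = preprocess_expression(
        mirna, clin, min_os_days=cfg.min_os_days, max_zero_frac=cfg.max_zero_frac
    )
    shared_counts = [s for s in gene_counts.sample_ids if s in set(clin_m.sample_ids)]
    counts = gene_counts.subset_samples(shared_counts)

    # --- differential expression & enrichment ------------------------------
    types = clin_m.subset(shared_counts).data.set_index("sample_id").loc[
        shared_counts, "sample_type"
    ]
    de = differential_expression(counts, types.to_numpy(), cfg)
    degs = de_gene_ids(de)
    if not degs:
        raise ValidationError("no differentially expressed genes; cannot continue")
    enriched = ora_enrichment(degs, counts.feature_ids, gene_sets, cfg)

    # --- negative regulation pairs (tumor samples only) ---------------------
    tumor_ids = [
        s for s in clin_m.tumor_samples().sample_ids if s in set(mirna_pp.sample_ids)
    ]
    gene_norm, _, _ = preprocess_expression(
        gene_counts,
        clin_m,
        min_os_days=cfg.min_os_days,
        max_zero_frac=cfg.max_zero_frac,
        keep_types=("TP",),
    )
    pairs = negative_pairs(
        mirna_pp.subset_samples(tumor_ids),
        gene_norm,
        validated_pairs,
        degs,
        cfg,
    )
    candidates = restrict_candidates(pairs, enriched, gene_sets)
    candidates = [c for c in candidates if c in mirna_pp.values.index]
    if not candidates:
        raise ValidationError("no candidate miRNAs present in the expression matrix")

    # --- survival-based selection (tumor samples with follow-up) ------------
    clin_t = clin_m.tumor_samples()
    time, event, surv_ids = clin_t.survival_arrays()
    expr_t = mirna_pp.subset_samples(surv_ids)
    cand_expr = expr_t.subset_features(candidates)
    screened = univariate_screen(
        cand_expr, time, event, screen_p=cfg.screen_p, adjust=cfg.screen_adjust
    )
    if not screened:
        raise ValidationError("no candidate survives the univariate survival screen")

    rank_matrix = None
    groups = None
    if len(screened) >= 2:
        rank_matrix = importance_rank_matrix(
            expr_t.subset_features(screened),
            time,
            event,
            B=cfg.importance_repeats,
            seed=cfg.child_seed("importance"),
        )
        k = min(cfg.cluster_k, len(screened))
        if k >= 2:
            groups, survivors = cluster_importance(rank_matrix, k=k)
        else:
            survivors = list(screened)
    else:
        survivors = list(screened)

    signature, trace = greedy_select(survivors, expr_t, time, event)
    if not signature:
        raise ValidationError("greedy selection kept no miRNA")

    # --- risk model ---------------------------------------------------------
    model = fit_risk_model(
        expr_t.subset_features(signature),
        clin_t,
        min_group_frac=cfg.min_group_frac,
        expression_scale=pp_report.get("scale", "unspecified"),
    )
    assignment = apply_model(model, expr_t, clin_t)
    eval_days = [y * DAYS_PER_YEAR for y in cfg.eval_years]
    report = evaluate_cohort(assignment, clin_t, eval_days)

    return DiscoveryResult(
        de_results=de,
        enriched_terms=enriched,
        retained_pairs=pairs,
        candidates=candidates,
        screened=screened,
        rank_matrix=rank_matrix,
        importance_groups=groups,
        ordered_survivors=survivors,
        signature=signature,
        trace=trace,
        model=model,
        mirna_expr=expr_t,
        clinical=clin_t,
        training_assignment=assignment,
        training_report=report,
        preprocess_report=pp_report,
    )


def apply_external(
    result_or_model: DiscoveryResult | SignatureModel,
    train_expr: ExpressionMatrix,
    external_expr: ExpressionMatrix,
    external_clinical: ClinicalTable,
    cfg: PipelineConfig | None = None,
) -> tuple[RiskAssignment, EvaluationReport]:
    """Score an external cohort with the fixed training model.

    The external matrix is first harmonized feature-by-feature onto the
    training scale (location-scale batch adjustment with the training
    cohort as reference), then scored with the training thresholds and
    cutoff; the cutoff is never recomputed.
    """
    cfg = cfg or PipelineConfig()
    model = (
        result_or_model.model
        if isinstance(result_or_model, DiscoveryResult)
        else result_or_model
    )
    clin = filter_samples(external_clinical, min_os_days=cfg.min_os_days, keep_types=("TP",))
    shared = [s for s in external_expr.sample_ids if s in set(clin.sample_ids)]
    ext = external_expr.subset_samples(shared)
    clin = clin.subset(shared)

    features = [f for f in train_expr.feature_ids if f in set(ext.feature_ids)]
    missing = [m for m in model.mirna_ids if m not in features]
    if missing:
        raise ValidationError(f"external cohort lacks signature miRNAs: {missing}")
    combined = ExpressionMatrix(
        pd.concat(
            [train_expr.subset_features(features).values, ext.subset_features(features).values],
            axis=1,
        ),
        kind="normalized",
    )
    labels = np.array(
        ["train"] * train_expr.n_samples + ["external"] * ext.n_samples
    )
    adjusted = batch_adjust(combined, labels, reference_batch="train")
    ext_adj = adjusted.subset_samples(ext.sample_ids)
    assignment = apply_model(model, ext_adj, clin)
    eval_days = [y * DAYS_PER_YEAR for y in cfg.eval_years]
    report = evaluate_cohort(assignment, clin, eval_days)
    return assignment, report
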