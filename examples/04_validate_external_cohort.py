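"""Transfer a fitted model to an independent, batch-distorted cohort.

The validation cohort follows the same biology but every feature is
shifted and scaled (a measurement batch effect). The pipeline first
harmonizes it onto the training expression scale, then scores it with
the FIXED training thresholds and cutoff — nothing is refit.
"""
import warnings

from mirisk import (
    PipelineConfig, SimConfig, apply_external, generate_cohort,
    generate_validation_cohort, make_gene_sets, make_validated_pairs,
    run_discovery,
)

cfg = SimConfig(n_tumor=300, m_mirna=120, g_genes=1200, n_signature=6,
                beta_range=(0.7, 1.1), seed=7)
mirna, genes, clinical, truth = generate_cohort(cfg)
pcfg = PipelineConfig(importance_repeats=100, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_discovery(mirna, genes, clinical, make_validated_pairs(cfg, truth),
                        make_gene_sets(cfg, truth), pcfg)

    v_expr, v_clin = generate_validation_cohort(
        cfg, truth, batch_shift=2.0, batch_scale=1.5, n_tumor=150
    )
    assignment, report = apply_external(res, res.mirna_expr, v_expr, v_clin, pcfg)

n_high = sum(g == "high" for g in assignment.group)
print(f"validation cohort: {len(assignment.sample_ids)} patients, "
      f"{n_high} high-risk at the training cutoff {res.model.cutoff:.3f}")
print(f"validation log-rank p (high vs low): {report.overall_logrank_p:.2e}")
print("validation IPCW AUC:", {f"{t/365.25:.0f}y": round(a, 3)
                               for t, a in report.auc_by_time.as_dict().items()})
# p < 0.05 here means the signature's prognostic value transfers across
# the batch shift using the original thresholds — the key validation claim.
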