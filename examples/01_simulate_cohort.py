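"""Generate a synthetic tumor cohort with a planted miRNA signature.

Builds a TCGA-style study: miRNA expression, gene counts, clinical
follow-up, and the ground truth (which miRNAs are prognostic, through
which thresholds, with which effect sizes).
"""
from mirisk import SimConfig, generate_cohort

cfg = SimConfig(n_tumor=300, n_normal=40, m_mirna=100, g_genes=800,
                n_signature=5, n_null_regulators=15, pairs_per_signature=3,
                seed=42)
mirna, genes, clinical, truth = generate_cohort(cfg)

tp = clinical.data[clinical.data.sample_type == "TP"]
print(f"cohort: {mirna.n_samples} samples ({len(tp)} tumor), "
      f"{mirna.n_features} miRNAs, {genes.n_features} genes")
print(f"censoring fraction: {1 - tp.os_event.mean():.2f}")
print(f"median follow-up: {tp.os_days.median():.0f} days")
print("planted signature (miRNA, true beta, true threshold):")
for sid in truth.signature_ids:
    print(f"  {sid}  beta={truth.true_beta[sid]:+.2f}  "
          f"theta={truth.true_threshold[sid]:.2f}")

# A negative beta means LOW expression of that miRNA is hazardous (the
# patient's hazard is multiplied by exp(|beta|) when expression falls
# below the threshold); a positive beta means HIGH expression is risky.
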