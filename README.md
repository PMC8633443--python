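# mirisk

Multi-strategy miRNA prognostic-signature selection and a threshold/β
risk-score model for overall survival, with a synthetic-cohort
simulator that makes the entire workflow testable without any data
download.

## The problem

Tumor cohorts such as TCGA lung adenocarcinoma profile hundreds of
miRNAs alongside patient survival. The goal is a small, portable miRNA
signature that splits patients into high- and low-risk groups with
significantly different overall survival (OS), and that transfers to an
independent cohort measured on a different platform. `mirisk` is a
library for researchers building or evaluating such signatures; its
public face is the importable API (plus a thin `mirisk` command-line
wrapper and the narrative scripts in `examples/`).

## The model

Each signature miRNA *i* carries an optimal expression threshold θᵢ —
the maximally selected log-rank cutpoint — and a coefficient βᵢ, the
Cox log hazard ratio of the indicator 1[xᵢ > θᵢ]. A patient scores

s<sub>i</sub> = |βᵢ| if βᵢ < 0 and xᵢ < θᵢ;  s<sub>i</sub> = βᵢ if βᵢ > 0 and xᵢ > θᵢ;  s<sub>i</sub> = 0 otherwise,

and the risk score is Σᵢ sᵢ ∈ [0, Σᵢ|βᵢ|]. The cohort is dichotomized
at the median training score; external cohorts are harmonized onto the
training expression scale and reuse that fixed cutoff.

The signature itself is selected in stages: differential expression
(tumor vs normal counts), validated miRNA→target pairs filtered to
negative Spearman correlation, restriction to functionally enriched
targets, a univariate log-rank screen, B-fold bootstrap
permutation-importance ranking around a multivariate Cox model,
hierarchical clustering of the rank matrix (dropping the "meaningless"
group), and greedy forward combination under the −log₁₀ likelihood-
ratio-p criterion. `docs/methods.md` documents every stage, its
defaults, and the numerical choices.

## Worked example

`examples/03_full_discovery.py` simulates a 300-patient cohort with 6
planted prognostic miRNAs among 120, runs the full pipeline, and
prints:

```
DE genes: 240, retained pairs: 230, candidates: 46, screened: 20
signature (6 miRNAs): mir-0040, mir-0012, mir-0030, mir-0023, mir-0028, mir-0084
planted miRNAs recovered: 5/6
risk-score cutoff (median training score): 1.324
training log-rank p (high vs low risk): 3.56e-15
training IPCW AUC: {'1y': 0.764, '3y': 0.805, '5y': 0.81}
  mir-0040: theta=6.49, beta=+0.612 (high expression is risky)
  mir-0012: theta=5.01, beta=-0.712 (low expression is risky)
  ...
```

Reading this: of 46 candidate miRNAs with functional support, 20 pass
the survival screen; the greedy stage keeps 6, of which 5 are truly
prognostic by construction. The fitted model separates the training
cohort at log-rank p ≈ 4e−15 and discriminates 1-year survival with
IPCW AUC 0.76. `examples/04_validate_external_cohort.py` then applies
the same model — fixed thresholds, fixed cutoff — to an independent
cohort whose features were shifted and rescaled by a batch effect, and
still separates it at p ≈ 7e−5.

The other examples cover the simulator (`01`), the survival primitives
(`02`), and the clinical evaluation battery — stage-stratified tests,
covariate associations, treatment-response contrasts (`05`).

## Command line

```bash
mirisk simulate --out data/ --with-validation
mirisk fit --mirna data/mirna_expression.tsv --gene-counts data/gene_counts.tsv \
      --clinical data/clinical.tsv --pairs data/validated_pairs.tsv \
      --gene-sets data/gene_sets.gmt --out run/
mirisk apply --model run/model.json --train-mirna run/mirna_preprocessed.tsv \
      --mirna data/validation_mirna_expression.tsv \
      --clinical data/validation_clinical.tsv --out val/
```

All formats are plain text: TSV matrices and tables, GMT gene sets,
JSON models (schema-versioned), YAML configs.

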