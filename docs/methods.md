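# Methods

## The model

`mirisk` implements a prognostic-signature workflow for overall survival
(OS) built around a *threshold/β risk score*. For a signature of k
miRNAs, each miRNA i carries an optimal expression threshold θᵢ and a
coefficient βᵢ; a patient with expression vector x receives

    sᵢ = |βᵢ|  if βᵢ < 0 and xᵢ < θᵢ      (low expression is risky)
    sᵢ =  βᵢ   if βᵢ > 0 and xᵢ > θᵢ      (high expression is risky)
    sᵢ =  0    otherwise

    risk score = Σᵢ sᵢ  ∈  [0, Σᵢ|βᵢ|]

with strict inequalities, so a value exactly at its threshold
contributes nothing. θᵢ is the maximally selected log-rank cutpoint
(exhaustive scan over midpoints between consecutive distinct values,
both sides constrained to hold ≥ `min_group_frac` of the cohort, ties
broken toward the median); βᵢ is the univariate Cox log hazard ratio of
the indicator 1[xᵢ > θᵢ], so β > 0 reads "high expression hazardous".
Patients are dichotomized at the median training score; external
cohorts reuse that fixed cutoff. Because every contribution is a
|β|-sized step, the score is scale-free given the thresholds, which is
what allows markers measured on different platforms to be summed.

## Signature selection

The signature is found in stages, each with its own statistical
contract:

1. **Candidate restriction.** Genes differentially expressed between
   tumor (TP) and normal (NT) samples are identified from raw counts
   (BH-adjusted p < 1e−3 and |log2FC| ≥ 1); validated miRNA→target
   pairs are kept when the target is a DE gene and the pair shows
   negative Spearman correlation across tumor samples (BH-adjusted
   p < 0.01); candidate miRNAs must additionally target a gene that
   belongs to at least one over-represented gene set (hypergeometric
   test over GMT sets, BH-adjusted p < 0.05).
2. **Univariate screen.** Each candidate is dichotomized at its median
   and tested by log-rank; candidates with p < 0.05 survive. The
   correction mode is configurable (`screen_adjust`: raw p by default,
   optionally BH across candidates). Raw p is the default because the
   downstream clustering stage is designed to absorb the resulting
   false positives, and a survivor screen that passes only the true
   signal leaves the "drop the worst importance cluster" step with
   nothing to drop but signal.
3. **Permutation-importance ranking.** B repeats (default 5000; the
   test suite and acceptance runs use B = 200): draw a bootstrap
   sample, fit a multivariate Cox model on the in-bag patients
   (median-dichotomized indicators; medians computed once on the full
   cohort), and record for each miRNA the drop in out-of-bag Harrell
   concordance when its OOB column is permuted. Drops are ranked within
   each repeat (largest drop = rank 1; ties broken by id), giving an
   m × B rank matrix whose columns are exact permutations of 1..m.
4. **Importance clustering.** The rank rows are clustered
   (agglomerative, Euclidean distance, complete linkage) into k = 3
   groups; groups are ordered by within-group median rank and the worst
   ("meaningless") group is dropped. Survivors are ordered by their
   per-miRNA median rank.
5. **Greedy combination.** Survivors are fed in order into a
   multivariate Cox model; a candidate is kept only when the model's
   −log10 likelihood-ratio p strictly increases. Ties and fit failures
   (collinearity, separation) reject the candidate.

## Survival primitives

Kaplan–Meier, the two-group log-rank test (hypergeometric variance,
chi-square(1), two-sided), Cox partial likelihood with Efron tie
correction maximized by damped Newton iterations (step halving;
convergence at gradient norm < 1e−8 or a machine-precision-flat
likelihood; separation reported as an explicit error naming the
covariate), Harrell's c over usable pairs (score ties count ½), and
cumulative/dynamic time-dependent AUC with inverse-probability-of-
censoring weights from the reverse Kaplan–Meier estimate. With no
censoring the IPCW AUC reduces exactly to the empirical AUC of cases
versus survivors. These are implemented in the package (the cutpoint
scan and the importance loop need thousands of cheap refits) and are
cross-checked in the test suite against lifelines and scikit-survival
to numerical precision. The likelihood-ratio p quantifies "prognostic
ability" throughout.

## Preprocessing

Order of operations: sample filter → zero filter → quantile
normalization → batch adjustment. Tumor samples with OS < 30 days are
excluded (deaths likely unrelated to disease); NT samples are exempt.
Features with zeros in *more than* 90% of samples are dropped (a
feature at exactly 90% is kept). Quantile normalization maps every
sample column onto the across-sample rank-mean distribution, with ties
receiving the mean of their ranks' reference values; counts are
log2(x+1)-transformed first and the scale is recorded in run metadata
and in the model file, so `apply_model` can refuse mismatched inputs.
Batch adjustment is exact per-feature location–scale harmonization:
each batch is standardized and rescaled to the pooled per-feature
moments (which leaves the pooled mean and variance unchanged), with a
`reference_batch` mode that instead maps other batches onto a chosen
batch's moments and leaves that batch untouched. The reference mode is
what the transfer path uses, so a model fitted on the training scale
applies unchanged. This adjuster deliberately omits empirical-Bayes
shrinkage across features: it is deterministic, dependency-free, and
sufficient for the contract (per-feature batch means equalized), at the
cost of noisier per-feature variance estimates in small batches.

## Differential expression stand-in

DE analysis is Welch's t on log2(normalized + 0.5) with median-of-ratios
size factors (geometric-mean-one normalization over genes with
all-positive counts). This is not a negative-binomial GLM: it trades
the NB likelihood's small-count efficiency for transparency and speed,
and its contract here is only a calibrated, ranked DE list under the
two published thresholds. Type-I error on null NB simulations
(dispersion 0.2, n = 50/50) is verified to sit within [0.03, 0.07] at
nominal 0.05.

Spearman p-values for the pair filter use the t approximation at all
sample sizes. The pipeline requires ≥ 10 shared samples; exhaustive
permutation enumeration is infeasible beyond n ≈ 9, and at the
pipeline's scale (hundreds of samples) the approximation is accurate.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at matrix level:

- **miRNA expression**: per-feature log-normal (log-mean U(1,3),
  log-sd U(0.3,0.8)), continuous and non-negative.
- **Prognostic structure**: `n_signature` planted miRNAs act through
  *step* effects — patient s is risky for miRNA i when its expression
  falls on the risky side of a true threshold placed at the
  `threshold_quantile` (default 0.5) of the feature's marginal; the
  hazard is `baseline_hazard · exp(Σᵢ |βᵢ| riskyᵢ(s))`, exact
  proportional hazards with identifiable cutpoints. |βᵢ| ~ U(beta_range)
  with random sign.
- **Survival**: exponential event times from the per-patient hazard,
  independent exponential censoring, observed time the minimum in whole
  days. Defaults `baseline_hazard = 5e-5`/day, `censor_rate =
  6.25e-4`/day yield ≈ 40% censoring and TCGA-like time scales (the
  censoring fraction depends only on rate ratios; the overall scale was
  chosen so that < 30-day deaths are rare, ~6%).
- **Null regulators and co-expression**: `n_null_regulators` additional
  miRNAs repress DE targets but carry no survival effect; a fraction
  (`frac_coexpressed`, default 0.5) is co-expressed with a random
  signature miRNA at correlation `coexpression_rho` (default 0.7) on
  the log scale. These surrogates are the realistic nuisance the
  multi-stage selection exists to reject: they pass the univariate
  screen through their correlation with true signal and must be weeded
  out by the conditional (multivariate) importance and greedy stages.
- **Genes**: negative-binomial counts (gamma–Poisson, dispersion 0.2),
  log-mean U(log 20, log 2000); a fraction `frac_de_genes` is shifted by
  ±`de_log2fc` in tumor vs normal (60% up). Each regulator miRNA
  (planted or null) represses `pairs_per_signature` DE genes: the
  gene's log2 mean declines linearly in the miRNA's standardized
  log-expression with slope `regulation_slope` plus Gaussian noise.
- **Clinical covariates**: stage I–IV assigned with probability
  increasing in the latent risk (`stage_risk_gradient` on a
  noisy latent scale; marginal frequencies ≈ 50/28/15/7%); chemotherapy
  assignment enriched in late stages; an optional risk-group-specific
  treatment hazard ratio plants a detectable benefit; age and sex are
  independent of risk (null controls for the evaluation battery).
- **Validation cohorts** re-use the identical per-feature parameters
  and planted truth (drawn from a dedicated seed stream), then apply
  `x → batch_scale·x + batch_shift` to every feature after survival is
  drawn — a pure measurement batch effect.

What the generator does **not** emulate: real TCGA marginal
distributions and miRNA naming, platform-specific zero inflation,
correlated gene–gene co-expression modules beyond the planted pairs,
competing risks, informative censoring, and time-varying effects.
Passing tests therefore certify the pipeline's statistical machinery
under its own assumptions, not performance on real LUAD data.

## Numerical choices and degenerate inputs

- All randomness flows from one config seed; stochastic stages derive
  child seeds via a content hash of the stage name (process-stable), so
  identical configs give byte-identical outputs.
- Cutpoint ties (equal log-rank statistic) resolve toward the median;
  risk-score ties at the cutoff go to the low-risk group.
- Median splits with ≥ 50% ties drop the candidate (logged) rather than
  fail the stage; constant features are dropped in the pair filter.
- Bootstrap repeats whose Cox fit fails are redrawn (≤ 3B attempts).
- Evaluation horizons beyond the last observed time, or with no cases
  or controls, yield NaN AUC with a warning rather than an error.
- Stage labels are normalized (IA/IB → I, …) before stratification;
  strata or treatment arms with < 5 patients per arm are skipped with a
  warning. Patients with more than one recorded therapy type are
  excluded from treatment contrasts.

## Scaled problem sizes

The test suite and the acceptance script run the pipeline at a desk
scale chosen to keep every stage identifiable: cohorts of 400 tumor
samples, 200 miRNAs (8 planted, |β| ∈ [0.5, 1.0], ~40% censoring),
2000 genes, and B = 200 importance repeats instead of the full 5000.
B = 200 keeps median ranks stable for cohorts of this size; the full
B = 5000 default remains for production runs. Calibration checks use
≥ 1000 null replicates per test family.

## Known limitations

- The location-scale batch adjuster assumes the batch effect is affine
  per feature; nonlinear platform effects would need the full
  empirical-Bayes machinery it replaces.
- The greedy combination is order-dependent by design (candidates enter
  by median importance rank); it makes no claim of finding the optimal
  subset.
- Maximally selected statistics are known to be anti-conservative if
  their p-values are reported unadjusted; here the cutpoint's log-rank
  statistic is used only for *selection*, and downstream inference
  (training/validation separation) is reported on the dichotomized
  score, which still inherits some optimism on the training cohort —
  the validation cohort provides the honest estimate.
- With heavy score discretization (few signature miRNAs), the median
  cutoff can leave the high-risk group much smaller than half the
  cohort.
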