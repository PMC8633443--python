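"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a TCGA-style two-cohort design at matrix level:

* miRNA expression is log-normal per feature; a planted subset of
  miRNAs is prognostic through *threshold-acting* effects: sample s is
  risky for miRNA i when its expression falls on the risky side of a
  true threshold (below it when beta_i < 0, above it when beta_i > 0),
  and the hazard is baseline * exp(sum_i |beta_i| * risky_i(s)) —
  exact proportional hazards with a step-function covariate, which makes
  the maximally selected cutpoint identifiable.
* Event times are exponential from that hazard, censoring times are
  independent exponential, observed time is the minimum (in whole days).
* Gene expression is negative-binomial counts; a fraction of genes is
  differentially expressed tumor vs normal, and each planted miRNA
  represses a handful of DE target genes: the gene's log2 mean declines
  linearly in the miRNA's standardized log-expression.
* Tumor stage is assigned with probability increasing in the latent
  risk; chemotherapy assignment is enriched in late stages and can
  carry a planted risk-group-specific hazard ratio.

A validation cohort re-draws samples from the same generative law
(identical per-feature parameters and planted truth) and then shifts
and scales every feature — the batch effect the harmonization step must
remove before the fitted model can be transferred.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    GroundTruth,
    ValidatedPair,
    ValidationError,
)

_PARAM_STREAM = 101  # fixed child-stream keys so cohorts share feature params
_TRAIN_STREAM = 202
_VALID_STREAM = 303
_AUX_STREAM = 404

_STAGES = ("I", "II", "III", "IV")
_STAGE_Z_QUANTILES = (0.50, 0.78, 0.93)  # I | II | III | IV boundaries
_CHEMO_P_BY_STAGE = {"I": 0.10, "II": 0.35, "III": 0.50, "IV": 0.60}


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream]))


def _feature_params(cfg: SimConfig) -> dict:
    """Per-feature generative parameters, deterministic given cfg.seed.

    Drawn from a dedicated stream so the training and validation cohorts
    share them exactly.
    """
    rng = _rng(cfg.seed, _PARAM_STREAM)
    mirna_mu = rng.uniform(1.0, 3.0, cfg.m_mirna)
    mirna_sd = rng.uniform(0.3, 0.8, cfg.m_mirna)
    n_reg = cfg.n_signature + cfg.n_null_regulators
    reg_idx = rng.choice(cfg.m_mirna, size=n_reg, replace=False)
    sig_idx = np.sort(reg_idx[: cfg.n_signature])
    null_idx = np.sort(reg_idx[cfg.n_signature :])
    reg_idx = np.concatenate([sig_idx, null_idx])
    lo, hi = cfg.beta_range
    beta_abs = rng.uniform(lo, hi, cfg.n_signature)
    beta_sign = rng.choice([-1.0, 1.0], size=cfg.n_signature)
    gene_log_mu = rng.uniform(np.log(20.0), np.log(2000.0), cfg.g_genes)
    n_de = int(round(cfg.frac_de_genes * cfg.g_genes))
    de_idx = np.sort(rng.choice(cfg.g_genes, size=n_de, replace=False))
    de_sign = rng.choice([-1.0, 1.0], size=n_de, p=[0.4, 0.6])
    # planted repressed targets: pairs_per_signature DE genes per regulator
    # miRNA (prognostic signature miRNAs first, then null regulators)
    n_pair_genes = n_reg * cfg.pairs_per_signature
    if n_pair_genes > n_de:
        raise ValidationError(
            "not enough DE genes for the requested planted pairs; "
            "raise frac_de_genes or g_genes"
        )
    pair_gene_pos = rng.choice(n_de, size=n_pair_genes, replace=False)
    # co-expression: a fraction of the null regulators track a random
    # signature miRNA (surrogate markers the multivariate stages must reject)
    n_coex = (
        int(round(cfg.frac_coexpressed * cfg.n_null_regulators))
        if cfg.n_signature
        else 0
    )
    if n_coex:
        which = rng.choice(cfg.n_null_regulators, size=n_coex, replace=False)
        coex_rows = null_idx[which]
        coex_partner_rows = sig_idx[rng.integers(0, cfg.n_signature, size=n_coex)]
    else:
        coex_rows = np.array([], dtype=int)
        coex_partner_rows = np.array([], dtype=int)
    return {
        "mirna_mu": mirna_mu,
        "mirna_sd": mirna_sd,
        "sig_idx": sig_idx,
        "reg_idx": reg_idx,
        "beta": beta_abs * beta_sign,
        "gene_log_mu": gene_log_mu,
        "de_idx": de_idx,
        "de_sign": de_sign,
        "pair_gene_pos": pair_gene_pos,
        "coex_rows": coex_rows,
        "coex_partner_rows": coex_partner_rows,
        "coex_rho": cfg.coexpression_rho,
    }


def mirna_ids(cfg: SimConfig) -> list[str]:
    return [f"mir-{i:04d}" for i in range(cfg.m_mirna)]


def gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene-{i:04d}" for i in range(cfg.g_genes)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _build_truth(cfg: SimConfig, params: dict) -> GroundTruth:
    m_ids = mirna_ids(cfg)
    g_ids = gene_ids(cfg)
    sig_ids = [m_ids[i] for i in params["sig_idx"]]
    true_beta = {sid: float(b) for sid, b in zip(sig_ids, params["beta"])}
    # true threshold at the stated quantile of the miRNA's marginal
    # (theoretical log-normal quantile, shared by both cohorts)
    z_q = stats.norm.ppf(cfg.threshold_quantile)
    thetas = np.exp(
        params["mirna_mu"][params["sig_idx"]]
        + params["mirna_sd"][params["sig_idx"]] * z_q
    )
    true_theta = {sid: float(t) for sid, t in zip(sig_ids, thetas)}
    de_ids = [g_ids[i] for i in params["de_idx"]]
    pair_genes = [de_ids[i] for i in params["pair_gene_pos"]]
    reg_ids = [m_ids[i] for i in params["reg_idx"]]
    planted = []
    for k, rid in enumerate(reg_ids):
        for g in pair_genes[k * cfg.pairs_per_signature : (k + 1) * cfg.pairs_per_signature]:
            planted.append(ValidatedPair(rid, g))
    return GroundTruth(
        signature_ids=sig_ids,
        true_beta=true_beta,
        true_threshold=true_theta,
        de_gene_ids=de_ids,
        planted_pairs=planted,
    )


def latent_risk(cfg: SimConfig, truth: GroundTruth, mirna_vals: pd.DataFrame) -> np.ndarray:
    """sum_i |beta_i| * risky_i(sample) on the raw expression scale."""
    r = np.zeros(mirna_vals.shape[1])
    for sid in truth.signature_ids:
        beta = truth.true_beta[sid]
        theta = truth.true_threshold[sid]
        x = mirna_vals.loc[sid].to_numpy(dtype=float)
        risky = (x < theta) if beta < 0 else (x > theta) if beta > 0 else np.zeros_like(x, bool)
        r += abs(beta) * risky
    return r


def _draw_mirna(rng, params, n) -> np.ndarray:
    m = len(params["mirna_mu"])
    z = rng.normal(size=(m, n))
    rows, partners = params["coex_rows"], params["coex_partner_rows"]
    if len(rows):
        rho = params["coex_rho"]
        z[rows] = rho * z[partners] + np.sqrt(1.0 - rho**2) * z[rows]
    logx = params["mirna_mu"][:, None] + params["mirna_sd"][:, None] * z
    return np.exp(logx)


def _draw_genes(cfg, rng, params, mirna_log_std: np.ndarray, is_tumor: bool, n) -> np.ndarray:
    """NB counts for n samples; mirna_log_std is (n_signature, n) standardized
    log-expression of the signature miRNAs, used for the planted repression."""
    log2mu = (params["gene_log_mu"] / np.log(2.0))[:, None] * np.ones((1, n))
    if is_tumor:
        log2mu[params["de_idx"], :] += (cfg.de_log2fc * params["de_sign"])[:, None]
        # planted negative regulation: gene log2 mean declines in its miRNA
        n_reg = len(params["reg_idx"])
        for k in range(n_reg):
            sl = slice(k * cfg.pairs_per_signature, (k + 1) * cfg.pairs_per_signature)
            gene_rows = params["de_idx"][params["pair_gene_pos"][sl]]
            noise = rng.normal(0.0, cfg.regulation_noise_sd, size=(len(gene_rows), n))
            log2mu[gene_rows, :] += cfg.regulation_slope * mirna_log_std[k][None, :] + noise
    mu = np.exp2(np.clip(log2mu, -2, 24))
    return _nb_counts(rng, mu, cfg.nb_dispersion)


def _assign_stage(rng, risk: np.ndarray, gradient: float) -> np.ndarray:
    sd = risk.std()
    z = gradient * (risk - risk.mean()) / sd if sd > 0 else np.zeros_like(risk)
    z = z + rng.normal(size=len(risk))
    cuts = np.quantile(z, _STAGE_Z_QUANTILES)
    return np.array([_STAGES[int(np.searchsorted(cuts, v, side="right"))] for v in z])


def _assign_treatment(rng, stages: np.ndarray) -> np.ndarray:
    out = []
    for st in stages:
        p = _CHEMO_P_BY_STAGE[st]
        if rng.random() < p:
            r = rng.random()
            if r < 0.45:
                out.append("chemotherapy")
            elif r < 0.9:
                out.append("carboplatin")
            else:
                out.append("chemotherapy+immunotherapy")  # multi-therapy, excluded later
        else:
            out.append("none")
    return np.array(out)


def _survival(cfg, rng, risk: np.ndarray, treated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hazard = cfg.baseline_hazard * np.exp(risk)
    high = risk > np.median(risk)
    hr = np.where(
        treated, np.where(high, cfg.chemo_hr_high_risk, cfg.chemo_hr_low_risk), 1.0
    )
    hazard = hazard * hr
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censor_rate, size=len(risk))
    os_days = np.ceil(np.minimum(t_event, t_cens)).astype(float)
    os_days = np.maximum(os_days, 1.0)
    os_event = (t_event <= t_cens).astype(int)
    return os_days, os_event


def _make_clinical(
    cfg, rng, sample_ids_tp, sample_ids_nt, os_days, os_event, stages, treatment, batch
) -> ClinicalTable:
    n_tp, n_nt = len(sample_ids_tp), len(sample_ids_nt)
    age = np.round(rng.normal(65, 10, n_tp + n_nt)).clip(30, 90)
    sex = rng.choice(["male", "female"], size=n_tp + n_nt)
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids_tp) + list(sample_ids_nt),
            "os_days": list(os_days) + [np.nan] * n_nt,
            "os_event": list(os_event) + [np.nan] * n_nt,
            "sample_type": ["TP"] * n_tp + ["NT"] * n_nt,
            "stage": list(stages) + [pd.NA] * n_nt,
            "age": age,
            "sex": sex,
            "batch": batch,
            "treatment": list(treatment) + ["none"] * n_nt,
        }
    )
    return ClinicalTable(df)


def generate_cohort(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate the training cohort: miRNA expression (TP+NT), gene counts
    (TP+NT), clinical table, and the planted ground truth."""
    params = _feature_params(cfg)
    truth = _build_truth(cfg, params)
    rng = _rng(cfg.seed, _TRAIN_STREAM)
    m_ids, g_ids = mirna_ids(cfg), gene_ids(cfg)
    tp_ids = [f"T{i:04d}" for i in range(cfg.n_tumor)]
    nt_ids = [f"N{i:04d}" for i in range(cfg.n_normal)]

    x_tp = _draw_mirna(rng, params, cfg.n_tumor)
    x_nt = _draw_mirna(rng, params, cfg.n_normal)
    mirna = ExpressionMatrix(
        pd.DataFrame(np.hstack([x_tp, x_nt]), index=m_ids, columns=tp_ids + nt_ids),
        kind="normalized",
    )

    reg_rows = params["reg_idx"]
    log_std_tp = (
        np.log(x_tp[reg_rows]) - params["mirna_mu"][reg_rows][:, None]
    ) / params["mirna_sd"][reg_rows][:, None]
    log_std_nt = (
        np.log(x_nt[reg_rows]) - params["mirna_mu"][reg_rows][:, None]
    ) / params["mirna_sd"][reg_rows][:, None]
    counts_tp = _draw_genes(cfg, rng, params, log_std_tp, True, cfg.n_tumor)
    counts_nt = _draw_genes(cfg, rng, params, log_std_nt, False, cfg.n_normal)
    genes = ExpressionMatrix(
        pd.DataFrame(
            np.hstack([counts_tp, counts_nt]), index=g_ids, columns=tp_ids + nt_ids
        ),
        kind="counts",
    )

    risk = latent_risk(cfg, truth, mirna.values.loc[:, tp_ids])
    stages = _assign_stage(rng, risk, cfg.stage_risk_gradient)
    treatment = _assign_treatment(rng, stages)
    treated = np.isin(treatment, ["chemotherapy", "carboplatin"])
    os_days, os_event = _survival(cfg, rng, risk, treated)
    clinical = _make_clinical(
        cfg, rng, tp_ids, nt_ids, os_days, os_event, stages, treatment, "train"
    )
    return mirna, genes, clinical, truth


def generate_validation_cohort(
    cfg: SimConfig,
    truth: GroundTruth,
    batch_shift: float | None = None,
    batch_scale: float | None = None,
    n_tumor: int | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Independent cohort from the same generative law, then batch-distorted.

    Every miRNA feature is transformed x -> batch_scale * x + batch_shift
    AFTER survival is drawn, so the biology is identical and only the
    measurement scale differs. Sample ids are disjoint from training.
    """
    shift = cfg.batch_shift if batch_shift is None else batch_shift
    scale = cfg.batch_scale if batch_scale is None else batch_scale
    if scale <= 0:
        raise ValidationError("batch_scale must be positive")
    n = cfg.n_tumor if n_tumor is None else n_tumor
    params = _feature_params(cfg)
    rng = _rng(cfg.seed, _VALID_STREAM)
    m_ids = mirna_ids(cfg)
    v_ids = [f"V{i:04d}" for i in range(n)]
    x = _draw_mirna(rng, params, n)
    raw = pd.DataFrame(x, index=m_ids, columns=v_ids)
    risk = latent_risk(cfg, truth, raw)
    stages = _assign_stage(rng, risk, cfg.stage_risk_gradient)
    treatment = _assign_treatment(rng, stages)
    treated = np.isin(treatment, ["chemotherapy", "carboplatin"])
    os_days, os_event = _survival(cfg, rng, risk, treated)
    clinical = _make_clinical(
        cfg, rng, v_ids, [], os_days, os_event, stages, treatment, "validation"
    )
    mirna = ExpressionMatrix(scale * raw + shift, kind="normalized")
    return mirna, clinical


def make_validated_pairs(
    cfg: SimConfig, truth: GroundTruth, n_decoys: int = 200
) -> list[ValidatedPair]:
    """Planted pairs plus random decoy miRNA->gene pairs (the stand-in for
    a validated-interaction database download)."""
    rng = _rng(cfg.seed, _AUX_STREAM)
    m_ids, g_ids = mirna_ids(cfg), gene_ids(cfg)
    planted = set((p.mirna_id, p.gene_id) for p in truth.planted_pairs)
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        m = m_ids[rng.integers(cfg.m_mirna)]
        g = g_ids[rng.integers(cfg.g_genes)]
        if (m, g) not in planted:
            decoys.add((m, g))
    out = list(truth.planted_pairs) + [ValidatedPair(m, g) for m, g in sorted(decoys)]
    return out


def make_gene_sets(
    cfg: SimConfig,
    truth: GroundTruth,
    n_functional: int = 5,
    n_random: int = 10,
    set_size: int = 40,
) -> GeneSetCollection:
    """Gene sets for the enrichment stage: ``n_functional`` sets built
    around DE genes (including the planted targets, so they come out
    enriched) and ``n_random`` sets drawn uniformly (nulls)."""
    rng = _rng(cfg.seed, _AUX_STREAM + 1)
    g_ids = gene_ids(cfg)
    de = list(truth.de_gene_ids)
    target_genes = sorted({p.gene_id for p in truth.planted_pairs})
    sets: dict[str, frozenset[str]] = {}
    for k in range(n_functional):
        members = set(target_genes[k::n_functional])
        n_extra_de = max(0, int(0.6 * (set_size - len(members))))
        if n_extra_de:
            members |= set(rng.choice(de, size=min(n_extra_de, len(de)), replace=False))
        n_bg = max(0, set_size - len(members))
        if n_bg:
            members |= set(rng.choice(g_ids, size=n_bg, replace=False))
        sets[f"functional_set_{k:02d}"] = frozenset(members)
    for k in range(n_random):
        members = rng.choice(g_ids, size=set_size, replace=False)
        sets[f"random_set_{k:02d}"] = frozenset(members)
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})
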