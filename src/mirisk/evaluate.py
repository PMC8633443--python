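"""Evaluation battery for a fitted risk assignment.

Covers discrimination (overall and stage-stratified Kaplan-Meier /
log-rank, time-dependent IPCW AUC at fixed horizons), association of the
score with clinical covariates (rank correlation with age, rank-sum
tests between sexes and stage pairs), and descriptive treatment-response
contrasts (chemotherapy vs none within late stages, high vs low risk
within treated patients, specific agent vs none within each risk
group). All tests are two-sided.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, ValidationError
from .risk import RiskAssignment
from .survival import AucCurve, logrank_test, time_dependent_auc

log = logging.getLogger(__name__)

_SUBSTAGE = {
    "IA": "I", "IB": "I", "IIA": "II", "IIB": "II",
    "IIIA": "III", "IIIB": "III", "IIIC": "III", "IVA": "IV", "IVB": "IV",
}


def normalize_stage(stage) -> object:
    """Map sub-stages (IA, IIB, ...) onto the main stages I-IV."""
    if pd.isna(stage):
        return pd.NA
    s = str(stage).strip().upper().replace("STAGE ", "")
    return _SUBSTAGE.get(s, s)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with continuity correction otherwise. Returns (U of
    the first sample, p). Completely tied data yields p = 1 with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both samples; p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Conditional two-sided Fisher's exact test on a 2x2 count table.

    p sums the hypergeometric probabilities of tables as or less likely
    than the observed one. The odds ratio is the sample estimate with a
    0.5 continuity correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("table has a zero margin")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return float(odds_ratio), float(p)


@dataclass
class EvaluationReport:
    overall_logrank_p: float
    overall_logrank_stat: float
    auc_by_time: AucCurve
    per_stage_logrank: dict[str, float] = field(default_factory=dict)
    score_age_corr: float = float("nan")
    score_age_p: float = float("nan")
    score_sex_p: float = float("nan")
    stage_score_tests: dict[str, float] = field(default_factory=dict)
    treatment_tests: dict[str, dict] = field(default_factory=dict)
    n_high: int = 0
    n_low: int = 0

    def to_dict(self) -> dict:
        return {
            "overall_logrank_p": self.overall_logrank_p,
            "overall_logrank_stat": self.overall_logrank_stat,
            "auc_by_time": self.auc_by_time.as_dict(),
            "per_stage_logrank": self.per_stage_logrank,
            "score_age_corr": self.score_age_corr,
            "score_age_p": self.score_age_p,
            "score_sex_p": self.score_sex_p,
            "stage_score_tests": self.stage_score_tests,
            "treatment_tests": self.treatment_tests,
            "n_high": self.n_high,
            "n_low": self.n_low,
        }


def _merged(assignment: RiskAssignment, clinical: ClinicalTable) -> pd.DataFrame:
    df = assignment.as_frame().merge(clinical.data, on="sample_id", how="inner")
    df = df[df["sample_type"] == "TP"]
    df = df.dropna(subset=["os_days", "os_event"])
    if df.empty:
        raise ValidationError("assignment and clinical table share no tumor samples")
    df["stage_norm"] = df["stage"].map(normalize_stage)
    return df


def evaluate_cohort(
    assignment: RiskAssignment,
    clinical: ClinicalTable,
    eval_times_days,
    min_stratum: int = 5,
) -> EvaluationReport:
    """Run the full evaluation battery for one cohort.

    Stage strata with fewer than ``min_stratum`` samples in either risk
    arm are skipped with a warning.
    """
    df = _merged(assignment, clinical)
    time = df["os_days"].to_numpy(dtype=float)
    event = df["os_event"].to_numpy(dtype=int)
    group = df["group"].to_numpy()
    score = df["score"].to_numpy(dtype=float)
    if len(np.unique(group)) < 2:
        raise ValidationError("risk assignment has a single group; nothing to compare")
    stat, p = logrank_test(time, event, group)
    auc = time_dependent_auc(score, time, event, eval_times_days)

    report = EvaluationReport(
        overall_logrank_p=p,
        overall_logrank_stat=stat,
        auc_by_time=auc,
        n_high=int((group == "high").sum()),
        n_low=int((group == "low").sum()),
    )

    # stage-stratified discrimination
    for stage in sorted(df["stage_norm"].dropna().unique()):
        sub = df[df["stage_norm"] == stage]
        counts = sub["group"].value_counts()
        if counts.get("high", 0) < min_stratum or counts.get("low", 0) < min_stratum:
            warnings.warn(f"stage {stage}: < {min_stratum} samples per arm; skipped")
            continue
        _, sp = logrank_test(
            sub["os_days"].to_numpy(float),
            sub["os_event"].to_numpy(int),
            sub["group"].to_numpy(),
        )
        report.per_stage_logrank[str(stage)] = float(sp)

    # score vs covariates
    ages = pd.to_numeric(df["age"], errors="coerce")
    ok = ages.notna()
    if ok.sum() >= 10 and np.ptp(score[ok.to_numpy()]) > 0:
        rho, ap = stats.spearmanr(score[ok.to_numpy()], ages[ok].to_numpy())
        report.score_age_corr, report.score_age_p = float(rho), float(ap)
    sexes = df["sex"].dropna().unique()
    if len(sexes) == 2:
        s0 = score[(df["sex"] == sexes[0]).to_numpy()]
        s1 = score[(df["sex"] == sexes[1]).to_numpy()]
        if len(s0) and len(s1):
            _, report.score_sex_p = wilcoxon_rank_sum(s0, s1)
    stages_present = sorted(df["stage_norm"].dropna().unique())
    for s_a, s_b in itertools.combinations(stages_present, 2):
        sa = score[(df["stage_norm"] == s_a).to_numpy()]
        sb = score[(df["stage_norm"] == s_b).to_numpy()]
        if len(sa) >= min_stratum and len(sb) >= min_stratum:
            _, sp = wilcoxon_rank_sum(sa, sb)
            report.stage_score_tests[f"{s_a}_vs_{s_b}"] = float(sp)

    report.treatment_tests = treatment_contrasts(assignment, clinical, min_arm=min_stratum)
    return report


def export_curves(
    assignment: RiskAssignment,
    clinical: ClinicalTable,
    auc: AucCurve,
    outdir,
) -> None:
    """Write plot-ready TSVs: Kaplan-Meier curves per risk group (overall
    and within each stage) and the AUC-by-time table."""
    from pathlib import Path

    from .survival import km_estimate

    outdir = Path(outdir)
    df = _merged(assignment, clinical)
    rows = []
    strata = [("all", df)] + [
        (str(s), df[df["stage_norm"] == s])
        for s in sorted(df["stage_norm"].dropna().unique())
    ]
    for stratum, sub in strata:
        for grp in ("high", "low"):
            gsub = sub[sub["group"] == grp]
            if len(gsub) < 2 or gsub["os_event"].sum() == 0:
                continue
            km = km_estimate(
                gsub["os_days"].to_numpy(float), gsub["os_event"].to_numpy(int)
            )
            for t, s in zip(km.times, km.survival):
                rows.append(
                    {"stratum": stratum, "group": grp, "time": t, "survival": s}
                )
    pd.DataFrame(rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"time_days": auc.eval_times, "auc": auc.auc}
    ).to_csv(outdir / "auc_by_time.tsv", sep="\t", index=False)


_MULTI_SEP = "+"


def treatment_contrasts(
    assignment: RiskAssignment,
    clinical: ClinicalTable,
    min_arm: int = 5,
) -> dict[str, dict]:
    """Descriptive survival contrasts around recorded treatment.

    Patients with more than one recorded therapy type (values joined
    with '+') are excluded. Contrasts: chemotherapy vs none within late
    stages (II+), high vs low risk within treated patients, and each
    specific agent vs none within each risk group. Arms below
    ``min_arm`` patients are skipped with a warning.
    """
    df = _merged(assignment, clinical)
    if "treatment" not in df.columns or df["treatment"].isna().all():
        warnings.warn("no treatment information; no contrasts computed")
        return {}
    df = df[df["treatment"].notna()]
    multi = df["treatment"].astype(str).str.contains(_MULTI_SEP, regex=False)
    df = df[~multi]
    treated = df["treatment"] != "none"
    if treated.sum() == 0:
        warnings.warn("no treated patients; no contrasts computed")
        return {}

    out: dict[str, dict] = {}

    def _logrank(sub: pd.DataFrame, labels: np.ndarray, name: str) -> None:
        counts = pd.Series(labels).value_counts()
        if len(counts) < 2 or (counts < min_arm).any():
            warnings.warn(f"contrast {name}: an arm has < {min_arm} patients; skipped")
            return
        t = sub["os_days"].to_numpy(float)
        e = sub["os_event"].to_numpy(int)
        if e.sum() == 0:
            warnings.warn(f"contrast {name}: no events; skipped")
            return
        stat, p = logrank_test(t, e, labels)
        out[name] = {
            "statistic": float(stat),
            "p": float(p),
            "n": {str(k): int(v) for k, v in counts.items()},
        }

    late = df[df["stage_norm"].isin(["II", "III", "IV"])]
    if len(late):
        _logrank(
            late,
            np.where(late["treatment"] != "none", "treated", "untreated"),
            "chemo_vs_none_late_stage",
        )
    tr = df[treated]
    if len(tr):
        _logrank(tr, tr["group"].to_numpy(), "high_vs_low_within_treated")
    for grp in ("low", "high"):
        sub = df[df["group"] == grp]
        if len(sub):
            _logrank(
                sub,
                np.where(sub["treatment"] != "none", "treated", "untreated"),
                f"treated_vs_none_{grp}_risk",
            )
    agents = sorted(set(df.loc[treated, "treatment"]))
    for agent in agents:
        for grp in ("low", "high"):
            sub = df[(df["group"] == grp) & (df["treatment"].isin([agent, "none"]))]
            if len(sub):
                _logrank(
                    sub,
                    np.where(sub["treatment"] == agent, agent, "none"),
                    f"{agent}_vs_none_{grp}_risk",
                )
    return out
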