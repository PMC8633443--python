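"""Kaplan-Meier, log-rank, Cox and time-dependent AUC on a toy cohort.

These are the primitives every later stage uses; here they are applied
directly to a simulated two-arm comparison.
"""
import numpy as np

from mirisk import cox_fit, km_estimate, logrank_test, time_dependent_auc

rng = np.random.default_rng(0)
n = 400
high_risk = rng.integers(0, 2, n)  # a known binary risk factor
t_event = rng.exponential(1.0 / (2e-3 * np.exp(0.8 * high_risk)))
t_censor = rng.exponential(800.0, n)
time = np.minimum(t_event, t_censor) + 0.5
event = (t_event <= t_censor).astype(int)

km = km_estimate(time[high_risk == 0], event[high_risk == 0])
print(f"1-year survival, low-risk arm: {km(365.25):.3f}")

stat, p = logrank_test(time, event, high_risk)
print(f"log-rank: chi2(1) = {stat:.1f}, p = {p:.2e}")

fit = cox_fit(high_risk.astype(float), time, event, names=["high_risk"])
print(f"Cox log hazard ratio: {fit.beta[0]:.3f} (se {fit.se[0]:.3f}; true 0.8)")

auc = time_dependent_auc(high_risk.astype(float), time, event, [365.25, 1095.75])
print("IPCW AUC at 1y / 3y:", [f"{a:.3f}" for a in auc.auc])
# AUC ~0.65-0.70 is typical for a single binary marker with this effect size.
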