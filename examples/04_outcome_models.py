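"""Relate palpation metrics to cannulation outcome (stable flashback).

Per skill tier: the empirical success probability with a 95% Wilson
interval, stratified univariate logistic models of stb on each force
metric, and monotone Hill-curve summaries of the significant predictors.
"""

import palpmetrics as pm

trials, _ = pm.generate_cohort(pm.CohortSpec(), seed=11)
table = pm.metrics_table([b for b, _ in trials])
ok = table[table.seg_status == "ok"]

print("success probability by skill tier:")
for _, r in pm.success_table(ok).iterrows():
    print(f"  {r.group}: {r.k}/{r.n} = {r.p_hat:.3f} "
          f"(95% CI {r.ci_lo:.3f}, {r.ci_hi:.3f})")

logit = pm.logistic_table(ok)
print("\nsignificant univariate predictors of success:")
sig = logit[(logit.p_wald < 0.05) & (~logit.separation)]
for _, r in sig.iterrows():
    print(f"  {r.stratum} {r.metric:>12}: slope {r.slope:+.4f}  p={r.p_wald:.3g}")

curves = pm.hill_fits(ok, logit)
print("\nHill-curve summaries (p(success) vs metric):")
for key, c in curves.items():
    print(f"  {key}: {c['direction']}, range [{c['p_min']:.2f}, {c['p_max']:.2f}], "
          f"half-point {c['k']:.2f}, coefficient {c['h']:.2f}")
# A decreasing curve means success probability falls as the metric grows
# (e.g. more idle time or touchpoints in low performers).
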