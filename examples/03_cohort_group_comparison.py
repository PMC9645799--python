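"""Generate a cohort and compare palpation metrics across skill tiers.

Subjects are labelled HP / MP / LP from expert GRS ratings; each performs
16 trials over the 4 fistula x 2 skin x 2 vibration conditions. The
pairwise Mann-Whitney table mirrors the standard reporting layout
(LP-HP, LP-MP, MP-HP with significance stars at raw p < .05/.01/.001).
"""

import palpmetrics as pm

spec = pm.CohortSpec(group_sizes={"HP": 5, "MP": 5, "LP": 5})
trials, _ = pm.generate_cohort(spec, seed=3)

table = pm.metrics_table([b for b, _ in trials])
ok = table[table.seg_status == "ok"]
print(f"{len(ok)}/{len(table)} trials auto-segmented")

comparisons = pm.compare_groups(ok)
lp_hp = comparisons[(comparisons.group_a == "LP") & (comparisons.group_b == "HP")]
print("\nLP vs HP (medians and Mann-Whitney):")
for _, r in lp_hp.iterrows():
    print(f"  {r.metric:>14}: {r.median_a:8.2f} v {r.median_b:8.2f}   "
          f"p={r.p:.2e} {r.star}")
# Expect lower-skill palpation to show more touchpoints, larger total
# force, longer path, and fewer near-motor touchpoints.
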