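"""Generate one synthetic palpation trial and look at what the sensors saw.

A trial emulates a clinician palpating a hemodialysis-access simulator:
rest, a train of fingertip presses searching for the fistula's vibrating
anastomosis, then gripping the needle. Ground truth records the events the
generator actually emitted.
"""

import palpmetrics as pm

profiles = pm.default_profiles()
layout = pm.default_layout()

bundle, truth = pm.generate_trial(
    profiles["LP"], layout, seed=42, trial_id="demo", grs=(5, 4)
)

print(f"trial {bundle.trial_id}: fistula {bundle.fistula_id}, "
      f"skin {bundle.skin}, vibration {bundle.vibration}")
print(f"channels: {sorted(bundle.channels)}")
print(f"true palpation window: {truth.t_start:.2f} .. {truth.t_end:.2f} s")
print(f"true touchpoints: {truth.metrics['touchpoints']} "
      f"(mean dwell {truth.metrics['mean_tpt']:.3f} s, "
      f"mean peak force {truth.metrics['mean_tpf']:.3f} N)")
print(f"true success probability {truth.p_success:.3f} -> stb = {truth.stb}")
# The stb flag is the cannulation outcome: 1 means stable blood flashback
# was sustained to the end of the trial.
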