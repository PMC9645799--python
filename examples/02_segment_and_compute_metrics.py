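"""Segment the palpation phase of a trial and compute the twelve metrics.

The window starts when index/middle force rises after a quiescent period
and ends when a thumb-force change coincides with needle movement (the
pickup for insertion). Touchpoints are peaks of the combined index+middle
force; the metrics summarize how long, how hard and where the subject
palpated.
"""

import palpmetrics as pm

profiles = pm.default_profiles()
layout = pm.default_layout()

bundle, truth = pm.generate_trial(profiles["HP"], layout, seed=7, grs=(7, 7))
resampled = pm.resample_to_grid(bundle, 100.0)  # common 100 Hz grid

window = pm.detect_palpation_window(resampled)
print(f"window [{window.T_start:.2f}, {window.T_end:.2f}] s "
      f"({window.method}, {window.status}); "
      f"truth [{truth.t_start:.2f}, {truth.t_end:.2f}] s")

touchpoints = pm.detect_touchpoints(resampled, window, layout)
metrics = pm.compute_trial_metrics(resampled, window, touchpoints, layout)

for name, value in metrics.as_dict().items():
    print(f"  {name:>14}: {value if value is None else round(value, 3)}")
# rcm (% of significant movements toward the motor) and rntp (% of
# touchpoints within 40 mm of it) capture how targeted the search was;
# dwell_time + idle_time always equals the window length.
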