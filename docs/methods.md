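# Methods

This note documents the models, parameter choices and numerical decisions
behind `palpmetrics`, and what the synthetic validation does and does not
establish about real recordings.

## Data model and resampling

A trial bundle carries ten sensor channels with heterogeneous native rates
(the hardware families involved — capacitive fingertip force sensors,
optical hand tracking, electromagnetic needle tracking, an IR flashback
detector — do not share a clock). All analysis runs on a common uniform
grid (default 100 Hz, configurable) spanning the intersection of the
channel time ranges. Continuous channels are linearly interpolated; source
gaps longer than `gap_max` (default 0.1 s) become missing samples rather
than being bridged, which operationalizes the "complete position data"
requirement for location metrics; the binary flashback channel is resampled
by previous-value hold. Resampling is idempotent at a fixed rate, and
write→read of the on-disk format (JSON metadata + `t,v` CSVs with 17
significant digits) is bit-exact.

Skill tiers come from two expert GRS ratings (1–7): HP iff palpation = 7
and overall = 7; LP iff palpation ≤ 5 and overall ≤ 4; otherwise MP. The
two rules are disjoint, so the 49-cell score grid is partitioned.

## Calibration

Fistula central axes are fitted to traced fingertip points by orthogonal
(total) least squares in the bed plane — the first principal component of
the centered cloud; the RMS perpendicular residual is `s2/sqrt(n)` from the
SVD. Traces are z-projected first because every downstream metric is
planar. A cloud whose principal-axis ratio is below 1.05 has no dominant
direction and is rejected rather than fitted. Motor (anastomosis)
locations are layout inputs, not estimated from the axis fit; the fitted
axis direction is exposed for future orientation metrics but consumed by
nothing.

## Segmentation

Forces are smoothed by a centered moving average (50 ms). The start is the
first sample where smoothed index or middle force exceeds, by
`start_force_delta` (0.10 N), the *minimum* over the most recent quiescent
window (1.0 s with peak-to-peak variation < `start_force_delta` on both
channels). Using the window minimum as the reference matters: a pulse
already rising inside a still-quiescent window would otherwise inflate its
own baseline and bias the start late. The end is the first sample after
the start where the trailing-window thumb-force peak-to-peak exceeds
`thumb_force_delta` (0.15 N) while the needle tip displaces at least
`needle_disp_threshold` (5 mm) within a centered `coincidence_window`
(0.5 s) — timestamping the thumb-change onset rather than the earliest
window containing the event, which would bias the end early by up to the
window length. All thresholds sit at the scale of fingertip-force noise
(~0.05 N) and needle jitter and are exposed in `SegmentationConfig`; ties
resolve to the earliest time. Trials with no qualifying start or end
return `no_start` / `no_end` and are excluded from metrics, mirroring the
manual-video-review fallback that such studies use; manual windows are
plain inputs.

## Touchpoints and metrics

Touchpoints are peaks of the combined index+middle force with prominence
≥ 0.05 N, absolute height ≥ 0.05 N and pairwise separation ≥ 0.10 s (the
higher peak wins a separation conflict). The height floor is a
contact-force threshold: over a long quiet stretch, band-limited sensor
noise can be locally "prominent" without any touch having occurred. Dwell
(TPT) is the full width at half prominence. Peak widths are measured on a
slice padded 1 s beyond the window — a peak abutting a window edge would
otherwise have its half-prominence crossing clipped — while only peaks
whose apex lies inside the window count.

TPT is thus an *operational* quantity: for overlapping pulses the
half-prominence width of the composite signal differs from the underlying
contact duration. The synthetic ground truth therefore records both the
latent event durations and the operational widths evaluated on the
noiseless signal; pipeline values converge to the latter as sensor noise
goes to zero.

Velocity for RCM uses positions smoothed with a 5-sample moving average and
central differences; the projection is onto the unit vector from the
current fingertip position to the motor (positive = toward). The 20 mm/s
significance threshold (RCM) and 40 mm radius with strict inequality
(RNTP) are constants of the metric definitions. RCM and RNTP are
*undefined* — not zero — when their denominators are empty, and undefined
values propagate as missing. Path length uses raw (unsmoothed) valid
frames; smoothing is applied only for velocity. Touchpoints without a
valid fingertip position keep their force information but are excluded
from RNTP and mean TPD; trials with any missing position frame inside the
window are excluded from location-metric group statistics
(`location_valid`).

`TotalForce = Σ TPT·TPF` has units N·s; reports keep the conventional
force label but the docstrings state the units.

## Outcome statistics

Group comparisons are trial-level Mann-Whitney U tests (pooling trials
ignores within-subject clustering, matching the reporting convention this
layout mirrors; a per-subject-median sensitivity mode exists but is off by
default), two-sided, starred at raw p < .05/.01/.001 with no
multiple-testing correction. The exact null distribution is used when both
samples have ≤ 8 observations without ties; otherwise the normal
approximation with tie and continuity corrections. Success probabilities
get 95% Wilson score intervals (the interval is always inside [0,1] and
behaves at k = 0 and k = n). Univariate logistic models are fitted by
Newton IRLS with Wald p-values; univariate perfect separation is detected
geometrically (a threshold on x splitting the classes) and flagged, with
coefficients suppressed. Hill curves are fitted to decile-binned empirical
success rates by weighted least squares with box constraints
(0 ≤ p_min, p_max ≤ 1, k inside the data range, h ∈ [0.1, 20]); a fitted
range below 0.05 or a Hill coefficient pinned at its bound is reported as
unidentifiable (`FitFailure`) rather than as parameters. At realistic
sample sizes the Hill coefficient carries ~15% sampling error per dataset,
so recovery checks use the median fit across a handful of replicates.

## Synthetic cohort generator

The generator is the study-conditions model, not a tuning knob. A trial
is: a quiescent rest (~2.5 s); a train of touchpoints whose count is
negative-binomial (dispersion 60), with lognormal dwells, peak forces and
inter-touch gaps; a fingertip that rests at each touch location and moves
in straight legs between them; and a needle-pickup event (0.8 N thumb ramp
+ 30 mm needle displacement) that ends palpation. Touch locations follow a
motor-biased random walk: each step mixes a unit pull toward the active
motor (weight `motor_bias`) with an isotropic random direction, softly
confined to the bed. The stable-flashback outcome is Bernoulli with a
logistic model on the trial's true metrics.

Default tier profiles are parameterized to published group-level central
values for the independently settable quantities — touchpoint count
20/15/13 (LP/MP/HP), mean dwell 0.326/0.386/0.350 s, mean peak force
0.305/0.322/0.267 N, idle time 6.73/6.04/5.05 s, walk steps sized so path
length ≈ 1373/1128/871 mm — and the motor bias (0.37/0.42/0.55) was
calibrated once, by simulating the walk alone, so median touch-to-motor
distance lands near 81/81/54 mm. Those published central values are not
mutually consistent as generator parameters (e.g. 20 touchpoints × 0.326 s
≠ the 8.96 s dwell tabulated alongside), so dwell, frequency, total force,
force range, RCM and RNTP are *emergent*; with a single-parameter walk the
emergent RCM sits near 52/54/58% rather than the published 66.7/66.7/75%,
with ordering and group separation preserved. Outcome-model coefficients
take the published signs and magnitudes for each tier's significant
predictors, centered at the profile's implied metric values, with
intercepts set to tier success rates 0.548/0.850/0.946.

Sensor noise is additive Gaussian (0.02 N force, 0.5 mm position before
filtering) band-limited by a 5-sample moving average — a sensor-bandwidth
model; unfiltered white noise at the grid rate would fabricate force peaks
and raw-frame path length that no physical force sensor or optical tracker
produces. Force channels are clipped at zero (sensors report non-negative
loads); without clipping, negative noise excursions at the pulse bases
inflate prominences and bias widths wide. Native rates are force 100 Hz,
fingertip 50 Hz, needle 80 Hz, flashback 20 Hz. Atypical behavioral modes
(`needle_moving`: the free hand fidgets with the needle throughout;
`thumb_only`: palpating with the thumb, outside the instrumented fingers)
reproduce the failure cases automatic segmentation must flag.

What passing the synthetic validation shows: the pipeline recovers the
generative model's per-group metric medians through the full sensor →
segmentation → detection → statistics path (worst median error ~5% at
default noise), flags the modelled failure modes, and reproduces the
expected significance pattern and success-probability ordering. What it
does not show: robustness to real-sensor artifacts absent from the model —
correlated inter-channel noise, dropouts, hand-model swaps in optical
tracking, drift — nor that the default thresholds are optimal for any
particular hardware. Problem sizes used by the test suite and acceptance
script (cohorts of 10 subjects × 16 trials per tier, 20 replicate cohorts,
200-trial segmentation studies) were chosen as the smallest designs whose
Monte-Carlo error is comfortably below the tolerances they check.

## Known limitations

- Comparisons pool trials within groups; subject-level random effects in
  the generator are mild (4% lognormal), and no mixed-effects outcome
  model is provided.
- The Wilson interval is a design choice; other proportion intervals give
  slightly different bounds at these sample sizes.
- The walk model couples touch-to-motor distance, near-touch ratio and
  movement-direction ratio through one bias parameter; matching all three
  published central values simultaneously is not possible in that family.
- Only univariate perfect separation is detected; quasi-separation with
  tied boundary values falls back on the optimizer's convergence flag.
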