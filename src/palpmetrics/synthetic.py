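"""Synthetic cohort generator with per-trial ground truth.

The raw human-subject recordings behind this kind of palpation study are
not publicly deposited, so the pipeline is exercised end-to-end on a
generative model of the task that emulates the behavioral structure of a
trial and records the exact events it emitted:

1. a quiescent pre-palpation period (hand at rest, forces at noise level);
2. a train of touchpoints: Gaussian force pulses on the index+middle
   channels (amplitude = peak force, FWHM = dwell), the fingertip resting
   at the touch location during each dwell and travelling in a straight
   line between consecutive touch locations during each gap;
3. touch locations following a motor-biased random walk: each step mixes a
   pull toward the active fistula's anastomosis motor (weight ``motor_bias``)
   with an isotropic random direction — higher bias yields closer
   touchpoints, more near-touchpoints and a higher ratio of correct
   movement;
4. a needle-pickup event ending palpation: thumb-force ramp coinciding with
   a needle-tip displacement;
5. a Bernoulli stable-flashback outcome drawn from a logistic model on the
   trial's true metrics.

Additive Gaussian sensor noise is band-limited with a short moving average
(physical force sensors and optical trackers are low-pass; unfiltered white
noise at the grid rate would fabricate force peaks and path length no real
sensor chain produces). Ground truth records the true window, the event
list and the noiseless values of all twelve metrics, so every pipeline
stage can be validated by parameter recovery. In the zero-noise limit the
pipeline metrics converge to the ground-truth values.

Default skill profiles (HP / MP / LP) are parameterized so their central
behavior matches published group-level values for the independently
settable quantities (touchpoint count 20/15/13, mean dwell-per-touchpoint
0.326/0.386/0.350 s, mean peak force 0.305/0.322/0.267 N, idle time
6.73/6.04/5.05 s, path length via the walk step, touch-to-motor distance
and movement ratio via the motor bias); the remaining metrics are emergent.
These are generator inputs, not claims of reproducing a human study.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .bundles import ChannelSeries, TrialBundle, write_trial_bundle
from .calibration import SimulatorLayout, default_layout
from .errors import DegenerateProfile
from .metrics import (
    METRIC_NAMES,
    PeakConfig,
    compute_rcm,
    compute_velocity_projection,
)

__all__ = [
    "SkillProfile",
    "GroundTruth",
    "default_profiles",
    "generate_trial",
    "generate_cohort",
    "CohortSpec",
]

#: native sampling rates of the emulated sensors, Hz
FORCE_RATE = 100.0
FINGER_RATE = 50.0
NEEDLE_RATE = 80.0
FLASHBACK_RATE = 20.0

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # Gaussian FWHM / sigma


@dataclass(frozen=True)
class SkillProfile:
    """Generator parameters for one skill tier."""

    name: str
    # touchpoint train
    touch_count_mean: float = 15.0  # negative-binomial mean
    touch_count_r: float = 60.0  # negative-binomial dispersion (size)
    tpt_mean: float = 0.35  # s, mean dwell per touchpoint (lognormal)
    tpt_sigma: float = 0.22
    tpf_mean: float = 0.30  # N, mean combined peak force (lognormal)
    tpf_sigma: float = 0.32
    idle_total_mean: float = 6.0  # s, expected total inter-touch time
    gap_sigma: float = 0.4
    quiescence_mean: float = 2.5  # s before the first touch
    quiescence_sigma: float = 0.12
    # trajectory (motor-biased walk)
    start_radius: float = 110.0  # mm, median first-touch distance to motor
    start_sigma: float = 0.30
    motor_bias: float = 0.30  # in [0, 1]
    step_mean: float = 75.0  # mm, mean walk step between touch locations
    step_sigma: float = 0.30
    # needle pickup
    pickup_thumb_force: float = 0.8  # N
    pickup_needle_disp: float = 30.0  # mm
    pickup_duration: float = 0.5  # s
    # outcome model: logit p = intercept + sum coef * (metric - center)
    stb_intercept: float = 1.0
    stb_coefs: dict = field(default_factory=dict)
    stb_centers: dict = field(default_factory=dict)
    # sensor noise (pre-bandwidth-filter standard deviations)
    noise_force: float = 0.02  # N
    noise_pos: float = 0.5  # mm
    # behavioral failure modes defeating automatic segmentation
    atypical: str | None = None  # None | "needle_moving" | "thumb_only"
    # per-subject lognormal heterogeneity (log-scale sd)
    subject_sigma: float = 0.04

    def __post_init__(self) -> None:
        if not (0.0 <= self.motor_bias <= 1.0):
            raise DegenerateProfile("motor_bias must be in [0, 1]")
        for f in ("tpt_mean", "tpf_mean", "idle_total_mean", "step_mean",
                  "quiescence_mean", "start_radius"):
            if not (getattr(self, f) > 0):
                raise DegenerateProfile(f"{f} must be positive")

    def implied_centers(self) -> dict[str, float]:
        """Analytic central metric values implied by the profile parameters."""
        n = self.touch_count_mean
        dwell = n * self.tpt_mean
        window = dwell + self.idle_total_mean
        return {
            "touchpoints": n,
            "mean_tpt": self.tpt_mean,
            "mean_tpf": self.tpf_mean,
            "dwell_time": dwell,
            "idle_time": self.idle_total_mean,
            "frequency": n / window,
            "total_force": n * self.tpt_mean * self.tpf_mean,
            "path_length": (n - 1) * self.step_mean,
        }


@dataclass
class GroundTruth:
    """Exact events and noiseless metric values of one generated trial."""

    t_start: float
    t_end: float
    touch_times: np.ndarray  # pulse centers, s
    touch_dwells: np.ndarray  # s (pulse FWHM)
    touch_forces: np.ndarray  # N (combined peak amplitude)
    touch_xy: np.ndarray  # (n, 2) mm
    touch_tpd: np.ndarray  # mm
    metrics: dict  # the twelve true metric values
    p_success: float
    stb: int


def default_profiles() -> dict[str, SkillProfile]:
    """The three default skill tiers (see module docstring for provenance)."""

    def logit(p: float) -> float:
        return math.log(p / (1 - p))

    lp = SkillProfile(
        name="LP",
        touch_count_mean=20.0,
        tpt_mean=0.326,
        tpf_mean=0.305,
        idle_total_mean=6.73,
        start_radius=115.0,
        motor_bias=0.37,
        step_mean=72.3,  # ~ path 1373 mm over 19 legs
        stb_intercept=logit(0.548),
        stb_coefs={
            "idle_time": -0.09415,
            "mean_tpt": 2.6702,
            "touchpoints": -0.05262,
            "frequency": -1.2012,
        },
    )
    mp = SkillProfile(
        name="MP",
        touch_count_mean=15.0,
        tpt_mean=0.386,
        tpf_mean=0.322,
        idle_total_mean=6.04,
        start_radius=115.0,
        motor_bias=0.42,
        step_mean=80.6,  # ~ path 1128 mm over 14 legs
        stb_intercept=logit(0.850),
        stb_coefs={
            "dwell_time": -0.04205,
            "total_force": -0.01877,
            "frequency": 0.7927,
        },
    )
    hp = SkillProfile(
        name="HP",
        touch_count_mean=13.0,
        tpt_mean=0.350,
        tpf_mean=0.267,
        idle_total_mean=5.05,
        start_radius=80.0,
        motor_bias=0.55,
        step_mean=72.6,  # ~ path 871 mm over 12 legs
        stb_intercept=logit(0.946),
        stb_coefs={},
    )
    out = {}
    for p in (lp, mp, hp):
        out[p.name] = replace(p, stb_centers=p.implied_centers())
    return out


# ---------------------------------------------------------------------------
# single-trial synthesis
# ---------------------------------------------------------------------------


def _lognormal_mean(rng, mean: float, sigma: float, size=None):
    """Lognormal draws with the requested arithmetic mean."""
    mu = math.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def _band_limited_noise(rng, sd: float, n: int, k: int = 5) -> np.ndarray:
    """White Gaussian noise low-passed by a k-sample moving average."""
    return uniform_filter1d(rng.normal(0.0, sd, n), size=k, mode="nearest")


def _walk_locations(rng, profile: SkillProfile, motor: np.ndarray,
                    bed_radius: float, n: int) -> np.ndarray:
    theta = rng.uniform(0, 2 * math.pi)
    r0 = profile.start_radius * rng.lognormal(0.0, profile.start_sigma)
    pts = np.empty((n, 2))
    pts[0] = motor + r0 * np.array([math.cos(theta), math.sin(theta)])
    lim = 0.93 * bed_radius
    for k in range(1, n):
        to_motor = motor - pts[k - 1]
        d = np.linalg.norm(to_motor)
        u_motor = to_motor / d if d > 1e-9 else np.zeros(2)
        a = rng.uniform(0, 2 * math.pi)
        u_rand = np.array([math.cos(a), math.sin(a)])
        mix = profile.motor_bias * u_motor + (1 - profile.motor_bias) * u_rand
        nrm = np.linalg.norm(mix)
        direction = mix / nrm if nrm > 1e-9 else u_rand
        step = _lognormal_mean(rng, profile.step_mean, profile.step_sigma)
        cand = pts[k - 1] + step * direction
        r = np.linalg.norm(cand)
        if r > lim:
            cand = cand * (lim / r)
        pts[k] = cand
    return pts


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def generate_trial(
    profile: SkillProfile,
    layout: SimulatorLayout | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    trial_id: str = "trial",
    subject_id: str = "subject",
    fistula_id: int = 1,
    skin: str = "thin",
    vibration: str = "low",
    grs: tuple[int, int] = (6, 5),
    subject_scale: dict | None = None,
) -> tuple[TrialBundle, GroundTruth]:
    """Synthesize one trial and its ground truth; deterministic given a seed."""
    if layout is None:
        layout = default_layout()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sc = subject_scale or {}
    motor = layout.motor(fistula_id)

    count_mean = profile.touch_count_mean * sc.get("count", 1.0)
    if count_mean <= 0:
        raise DegenerateProfile("touch_count_mean must be positive")
    p_nb = profile.touch_count_r / (profile.touch_count_r + count_mean)
    n = max(1, int(rng.negative_binomial(profile.touch_count_r, p_nb)))

    dwells = _lognormal_mean(rng, profile.tpt_mean * sc.get("tpt", 1.0),
                             profile.tpt_sigma, n)
    peaks = _lognormal_mean(rng, profile.tpf_mean * sc.get("tpf", 1.0),
                            profile.tpf_sigma, n)
    gaps = _lognormal_mean(
        rng, profile.idle_total_mean * sc.get("idle", 1.0) / n, profile.gap_sigma, n
    )
    quiescence = _lognormal_mean(rng, profile.quiescence_mean, profile.quiescence_sigma)
    quiescence = max(quiescence, 1.5)  # keep a resolvable pre-palpation rest

    onsets = np.empty(n)
    onsets[0] = quiescence
    for k in range(1, n):
        onsets[k] = onsets[k - 1] + dwells[k - 1] + gaps[k - 1]
    centers = onsets + dwells / 2.0
    t_pickup = onsets[-1] + dwells[-1] + gaps[-1]
    t_total = t_pickup + 3.0

    locs = _walk_locations(rng, profile, motor, layout.bed_radius, n)
    tpd = np.linalg.norm(locs - motor, axis=1)

    # --- force channels (100 Hz native) -----------------------------------
    tf = np.arange(0.0, t_total, 1.0 / FORCE_RATE)
    sig = dwells / _FWHM
    pulse_matrix = peaks[None, :] * np.exp(
        -0.5 * ((tf[:, None] - centers[None, :]) / sig[None, :]) ** 2
    )
    split = rng.uniform(0.75, 0.95, n)
    if profile.atypical == "thumb_only":
        f_index_true = np.zeros_like(tf)
        f_middle_true = np.zeros_like(tf)
        f_thumb_true = pulse_matrix.sum(axis=1)
    else:
        f_index_true = (pulse_matrix * split[None, :]).sum(axis=1)
        f_middle_true = (pulse_matrix * (1 - split)[None, :]).sum(axis=1)
        f_thumb_true = np.full_like(tf, 0.04) + 0.015 * np.sin(2 * math.pi * 0.2 * tf)

    if profile.atypical != "needle_moving":
        # thumb grip ramp at pickup
        ramp = np.clip((tf - t_pickup) / 0.3, 0.0, 1.0)
        f_thumb_true = f_thumb_true + profile.pickup_thumb_force * ramp

    def noisy(x):
        # force sensors report non-negative loads
        return np.maximum(x + _band_limited_noise(rng, profile.noise_force, len(x)), 0.0)

    f_index = noisy(f_index_true)
    f_middle = noisy(f_middle_true)
    f_thumb = noisy(f_thumb_true)

    # --- fingertip trajectory (50 Hz native) ------------------------------
    bp_t = [0.0]
    bp_xy = [locs[0]]
    for k in range(n):
        bp_t += [onsets[k], onsets[k] + dwells[k]]
        bp_xy += [locs[k], locs[k]]
    bp_t.append(t_total)
    bp_xy.append(locs[-1])
    bp_t = np.asarray(bp_t)
    bp_xy = np.asarray(bp_xy)
    tp_ = np.arange(0.0, t_total, 1.0 / FINGER_RATE)
    x_true = np.interp(tp_, bp_t, bp_xy[:, 0])
    y_true = np.interp(tp_, bp_t, bp_xy[:, 1])
    finger_x = x_true + _band_limited_noise(rng, profile.noise_pos, len(tp_))
    finger_y = y_true + _band_limited_noise(rng, profile.noise_pos, len(tp_))
    finger_z = 5.0 + _band_limited_noise(rng, profile.noise_pos, len(tp_))

    # --- needle (80 Hz native) ---------------------------------------------
    tn = np.arange(0.0, t_total, 1.0 / NEEDLE_RATE)
    base = np.array([layout.bed_radius + 30.0, 0.0, 15.0])
    needle = np.tile(base, (len(tn), 1)).astype(float)
    if profile.atypical == "needle_moving":
        # the free hand fidgets with the needle throughout the trial
        v = rng.normal(0.0, 1.0, (len(tn), 3))
        v = uniform_filter1d(v, size=40, axis=0, mode="nearest")
        v *= 25.0 / max(1e-9, np.mean(np.linalg.norm(v, axis=1)))
        needle = needle + np.cumsum(v / NEEDLE_RATE, axis=0)
    else:
        u = rng.normal(0.0, 1.0, 3)
        u[2] = abs(u[2])  # lift off the bed
        u /= np.linalg.norm(u)
        prog = np.clip((tn - t_pickup) / profile.pickup_duration, 0.0, None)
        needle = needle + profile.pickup_needle_disp * np.minimum(prog, 1.0)[:, None] * u
        drift = 20.0 * np.clip(prog - 1.0, 0.0, None)[:, None] * u
        needle = needle + drift
    for j in range(3):
        needle[:, j] += _band_limited_noise(rng, profile.noise_pos, len(tn))

    # --- true metrics ------------------------------------------------------
    t_start, t_end = float(onsets[0]), float(t_pickup)
    window = t_end - t_start
    in_win = (tf >= t_start) & (tf <= t_end)
    combined_true = f_index_true + f_middle_true
    if profile.atypical == "thumb_only":
        combined_true = f_thumb_true
    grid = np.arange(t_start, t_end, 0.01)
    gx = np.interp(grid, bp_t, bp_xy[:, 0])
    gy = np.interp(grid, bp_t, bp_xy[:, 1])
    if len(grid) >= 3:
        proj = compute_velocity_projection(grid, gx, gy, motor)
        rcm_true = compute_rcm(proj)
    else:
        rcm_true = None
    # Time/force metric truth is the metric's own operational definition
    # (half-prominence peak widths) evaluated on the NOISELESS force signal:
    # the sigma -> 0 limit of the pipeline. The latent generated dwells are
    # kept alongside in the GroundTruth event arrays; they coincide with the
    # measured widths only for well-separated pulses.
    from scipy.signal import find_peaks, peak_widths

    pk_cfg = PeakConfig()
    in_pad = (tf >= t_start - 1.0) & (tf <= t_end + 1.0)
    xp = combined_true[in_pad]
    tf_pad = tf[in_pad]
    pk, props = find_peaks(
        xp,
        height=pk_cfg.min_prominence,
        prominence=pk_cfg.min_prominence,
        distance=max(1, int(round(pk_cfg.min_separation * FORCE_RATE))),
    )
    keep = (tf_pad[pk] >= t_start - 1e-9) & (tf_pad[pk] <= t_end + 1e-9)
    pk = pk[keep]
    props = {k: v[keep] for k, v in props.items()}
    widths_true = peak_widths(
        xp, pk, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )[0] / FORCE_RATE
    peak_vals_true = xp[pk]
    n_true = len(pk)
    dwell_total = float(widths_true.sum())
    true_metrics = {
        "touchpoints": n_true,
        "frequency": n_true / window,
        "total_force": float(np.sum(widths_true * peak_vals_true)),
        "force_range": float(np.ptp(combined_true[in_win])) if in_win.any() else np.nan,
        "dwell_time": dwell_total,
        "idle_time": window - dwell_total,
        "path_length": float(np.sum(np.linalg.norm(np.diff(locs, axis=0), axis=1))),
        "rcm": rcm_true,
        "rntp": 100.0 * float(np.mean(tpd < 40.0)),
        "mean_tpt": float(widths_true.mean()) if n_true else np.nan,
        "mean_tpf": float(peak_vals_true.mean()) if n_true else np.nan,
        "mean_tpd": float(tpd.mean()),
    }

    z = profile.stb_intercept + sum(
        c * (true_metrics[m] - profile.stb_centers.get(m, 0.0))
        for m, c in profile.stb_coefs.items()
    )
    p_success = _sigmoid(z)
    stb = int(rng.random() < p_success)

    # --- flashback (20 Hz native) ------------------------------------------
    tb = np.arange(0.0, t_total, 1.0 / FLASHBACK_RATE)
    flash = np.zeros_like(tb)
    if stb:
        flash[tb >= t_total - 2.5] = 1.0

    channels = {
        "force_thumb": ChannelSeries("force_thumb", tf, f_thumb),
        "force_index": ChannelSeries("force_index", tf, f_index),
        "force_middle": ChannelSeries("force_middle", tf, f_middle),
        "finger_x": ChannelSeries("finger_x", tp_, finger_x),
        "finger_y": ChannelSeries("finger_y", tp_, finger_y),
        "finger_z": ChannelSeries("finger_z", tp_, finger_z),
        "needle_x": ChannelSeries("needle_x", tn, needle[:, 0]),
        "needle_y": ChannelSeries("needle_y", tn, needle[:, 1]),
        "needle_z": ChannelSeries("needle_z", tn, needle[:, 2]),
        "flashback": ChannelSeries("flashback", tb, flash),
    }
    bundle = TrialBundle(
        trial_id=trial_id,
        subject_id=subject_id,
        fistula_id=fistula_id,
        skin=skin,
        vibration=vibration,
        grs_palpation=grs[0],
        grs_overall=grs[1],
        stb=stb,
        channels=channels,
    )
    gt = GroundTruth(
        t_start=t_start,
        t_end=t_end,
        touch_times=centers,
        touch_dwells=dwells,
        touch_forces=peaks,
        touch_xy=locs,
        touch_tpd=tpd,
        metrics=true_metrics,
        p_success=p_success,
        stb=stb,
    )
    return bundle, gt


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_CONDITIONS = tuple(
    itertools.product((1, 2, 3, 4), ("thin", "thick"), ("low", "high"))
)

_GRS_CHOICES = {
    "HP": ((7, 7),),
    "MP": ((6, 5), (6, 6), (7, 6), (6, 4), (7, 5)),
    "LP": ((5, 4), (4, 3), (3, 2), (5, 3), (4, 4)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study design: subjects per skill tier and trials per subject."""

    group_sizes: dict = field(
        default_factory=lambda: {"HP": 10, "MP": 10, "LP": 10}
    )
    trials_per_subject: int = 16

    def __post_init__(self) -> None:
        if self.trials_per_subject < 1 or any(v < 1 for v in self.group_sizes.values()):
            raise DegenerateProfile("counts must be >= 1")


def generate_cohort(
    spec: CohortSpec | None = None,
    profiles: dict[str, SkillProfile] | None = None,
    layout: SimulatorLayout | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[TrialBundle, GroundTruth]], dict]:
    """Generate a full cohort; optionally write it as a bundle-directory tree.

    Each subject performs ``trials_per_subject`` trials; when that is 16,
    the condition sequence is a seeded random permutation of the 16
    fistula x skin x vibration combinations (otherwise conditions cycle
    through a permuted deck). GRS scores are assigned consistently with the
    subject's tier so skill classification recovers the intended groups.
    Per-trial randomness is spawned from one root seed, so cohorts are
    reproducible and individual trials regenerable.
    """
    spec = spec or CohortSpec()
    profiles = profiles or default_profiles()
    layout = layout or default_layout()
    root = np.random.SeedSequence(seed)

    trials: list[tuple[TrialBundle, GroundTruth]] = []
    index = {"seed": seed, "trials": []}
    groups = sorted(spec.group_sizes)
    subj_seeds = root.spawn(sum(spec.group_sizes[g] for g in groups))
    si = 0
    for g in groups:
        profile = profiles[g]
        for s in range(spec.group_sizes[g]):
            subj_ss = subj_seeds[si]
            si += 1
            subj_rng = np.random.default_rng(subj_ss)
            subject_id = f"{g}{s + 1:02d}"
            grs = _GRS_CHOICES[g][subj_rng.integers(len(_GRS_CHOICES[g]))]
            sig = profile.subject_sigma
            scale = {
                k: float(subj_rng.lognormal(0.0, sig))
                for k in ("count", "tpt", "tpf", "idle")
            }
            deck = list(_CONDITIONS)
            subj_rng.shuffle(deck)
            conditions = list(itertools.islice(
                itertools.cycle(deck), spec.trials_per_subject
            ))
            trial_seeds = subj_ss.spawn(spec.trials_per_subject)
            for k, (fid, skin, vib) in enumerate(conditions):
                trial_id = f"{subject_id}_t{k + 1:02d}"
                bundle, gt = generate_trial(
                    profile,
                    layout,
                    np.random.default_rng(trial_seeds[k]),
                    trial_id=trial_id,
                    subject_id=subject_id,
                    fistula_id=fid,
                    skin=skin,
                    vibration=vib,
                    grs=grs,
                    subject_scale=scale,
                )
                trials.append((bundle, gt))
                index["trials"].append(
                    {
                        "trial_id": trial_id,
                        "subject_id": subject_id,
                        "group": g,
                        "t_start": gt.t_start,
                        "t_end": gt.t_end,
                        "p_success": gt.p_success,
                        "stb": gt.stb,
                        "metrics": {
                            m: (None if gt.metrics[m] is None else float(gt.metrics[m]))
                            for m in METRIC_NAMES
                        },
                    }
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for bundle, _ in trials:
            write_trial_bundle(bundle, out_dir / bundle.trial_id)
        with open(out_dir / "cohort.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"schema_version": 1, "trials": [b.trial_id for b, _ in trials]},
                fh, indent=1,
            )
            fh.write("\n")
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(index, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return trials, index
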