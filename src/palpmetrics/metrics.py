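"""Touchpoint detection and the twelve per-trial palpation metrics.

A *touchpoint* is one episode of applied fingertip pressure, identified as a
peak of the combined index+middle force signal within the palpation window.
Per touchpoint we measure TPT (dwell: full width of the force peak at half
prominence, s), TPF (combined force at the peak sample, N) and TPD (planar
distance from the fingertip location at the peak to the active fistula's
anastomosis motor, mm).

Per trial the twelve metrics are: Touchpoints (count), Frequency
(count / window length, Hz), Total Force (sum of TPT x TPF over
touchpoints, N.s — note the product of a time and a force; conventionally
tabulated under a "(N)" label), Force Range (max - min combined force in
the window, N), Dwell Time (sum of TPT, s), Idle Time (window length minus
dwell, s), Path Length (planar distance travelled by the fingertip, mm),
RCM (ratio of correct movement: share of significant velocity projections,
|V_p| > 20 mm/s, directed toward the motor, %), RNTP (ratio of near
touchpoints: share of located touchpoints strictly within 40 mm of the
motor, %), and the per-trial means of TPT, TPF and TPD.

All location computations are planar (bed-plane x, y). RCM's 20 mm/s
significant-movement threshold and RNTP's 40 mm radius are fixed constants
of the metric definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .bundles import TrialBundle
from .calibration import SimulatorLayout
from .errors import EmptyWindow, NotResampled, TooFewFrames
from .segmentation import PalpationWindow

__all__ = [
    "PeakConfig",
    "Touchpoint",
    "ProjectionSeries",
    "TrialMetrics",
    "detect_touchpoints",
    "compute_velocity_projection",
    "compute_rcm",
    "compute_rntp",
    "compute_trial_metrics",
    "METRIC_NAMES",
]

#: canonical per-trial metric column order
METRIC_NAMES = (
    "touchpoints",
    "frequency",
    "total_force",
    "force_range",
    "dwell_time",
    "idle_time",
    "path_length",
    "rcm",
    "rntp",
    "mean_tpt",
    "mean_tpf",
    "mean_tpd",
)


@dataclass(frozen=True)
class PeakConfig:
    """Touchpoint-detection parameters.

    ``min_prominence`` and ``min_separation`` govern peak picking and sit at
    the scale of fingertip-force noise; ``rcm_speed_threshold`` (20 mm/s)
    and ``rntp_radius`` (40 mm) are the fixed constants of the RCM and RNTP
    definitions and should not normally be changed.
    """

    min_prominence: float = 0.05  # N
    min_separation: float = 0.10  # s
    width_reference: str = "half_prominence"
    rcm_speed_threshold: float = 20.0  # mm/s
    rntp_radius: float = 40.0  # mm

    def __post_init__(self) -> None:
        if self.min_prominence <= 0 or self.min_separation <= 0:
            raise ValueError("peak parameters must be positive")
        if self.width_reference != "half_prominence":
            raise ValueError("only half_prominence width is supported")


@dataclass(frozen=True)
class Touchpoint:
    """One detected force peak."""

    t_tp: float  # s, peak time
    TPT: float  # s, dwell (full width at half prominence)
    TPF: float  # N, combined index+middle force at the peak
    x_tp: float | None = None  # mm; None when fingertip position missing
    y_tp: float | None = None
    TPD: float | None = None  # mm, distance to the active motor

    @property
    def located(self) -> bool:
        return self.TPD is not None


@dataclass(frozen=True)
class ProjectionSeries:
    """Velocity projected onto the fingertip-to-motor direction, per frame.

    Positive values mean motion toward the motor. Frames with missing
    position are NaN.
    """

    t: np.ndarray
    V_p: np.ndarray  # mm/s


@dataclass(frozen=True)
class TrialMetrics:
    """The twelve per-trial palpation metrics.

    ``rcm``, ``rntp`` and ``mean_tpd`` are None when undefined (no
    significant movement / no located touchpoint). ``location_valid`` marks
    trials with complete fingertip position data inside the window; only
    those enter location-metric group statistics.
    """

    touchpoints: int
    frequency: float  # Hz
    total_force: float  # N.s (sum TPT*TPF; tabulated under a "(N)" label)
    force_range: float  # N
    dwell_time: float  # s
    idle_time: float  # s
    path_length: float  # mm
    rcm: float | None  # %
    rntp: float | None  # %
    mean_tpt: float  # s
    mean_tpf: float  # N
    mean_tpd: float | None  # mm
    location_valid: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES} | {
            "location_valid": self.location_valid
        }


def _window_slice(bundle: TrialBundle, window: PalpationWindow) -> slice:
    if bundle.grid_rate is None:
        raise NotResampled(f"trial {bundle.trial_id}: resample_to_grid first")
    if not np.isfinite(window.T_start) or not np.isfinite(window.T_end):
        raise EmptyWindow(f"trial {bundle.trial_id}: window not ok")
    if window.T_end <= window.T_start:
        raise EmptyWindow(
            f"trial {bundle.trial_id}: T_end {window.T_end} <= T_start {window.T_start}"
        )
    t = next(iter(bundle.channels.values())).t
    i0 = int(np.searchsorted(t, window.T_start - 1e-9, side="left"))
    i1 = int(np.searchsorted(t, window.T_end + 1e-9, side="right"))
    if i1 - i0 < 2:
        raise EmptyWindow(f"trial {bundle.trial_id}: window contains < 2 samples")
    return slice(i0, i1)


def detect_touchpoints(
    bundle: TrialBundle,
    window: PalpationWindow,
    layout: SimulatorLayout,
    cfg: PeakConfig = PeakConfig(),
) -> list[Touchpoint]:
    """Detect touchpoints as prominent peaks of the combined index+middle force.

    Peaks must have prominence >= ``min_prominence`` and pairwise separation
    >= ``min_separation`` (the higher peak wins a separation conflict). TPT
    is the full width at half prominence; TPF the combined force at the peak
    sample. Fingertip position at the peak sample supplies (x_tp, y_tp) and
    TPD; a missing position leaves the location fields unset but keeps the
    touchpoint for the force metrics.
    """
    sl = _window_slice(bundle, window)
    f_ind, f_mid = bundle.require("force_index", "force_middle")
    rate = bundle.grid_rate
    # widths are a property of the peak, so they are measured on a slice
    # padded beyond the window (otherwise a peak abutting T_start/T_end has
    # its half-prominence crossing clipped); only peaks whose apex lies
    # inside the window become touchpoints
    margin = int(round(1.0 * rate))
    pad = slice(max(0, sl.start - margin), min(len(f_ind.t), sl.stop + margin))
    t = f_ind.t[pad]
    combined = np.nan_to_num(f_ind.v[pad]) + np.nan_to_num(f_mid.v[pad])
    distance = max(1, int(round(cfg.min_separation * rate)))
    # the height floor doubles as a contact-force threshold: a genuine touch
    # must rise above the unloaded-sensor baseline, not merely be locally
    # prominent relative to a long quiet stretch of noise
    peaks, props = find_peaks(
        combined, height=cfg.min_prominence, prominence=cfg.min_prominence,
        distance=distance,
    )
    inside = (t[peaks] >= window.T_start - 1e-9) & (t[peaks] <= window.T_end + 1e-9)
    peaks = peaks[inside]
    if peaks.size == 0:
        return []
    props = {k: v[inside] for k, v in props.items()}
    widths = peak_widths(
        combined, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )[0]

    fx, fy = bundle.require("finger_x", "finger_y")
    fx, fy = fx.v[pad], fy.v[pad]
    motor = layout.motor(bundle.fistula_id)

    out: list[Touchpoint] = []
    for p, w in zip(peaks, widths):
        x, y = fx[p], fy[p]
        if np.isfinite(x) and np.isfinite(y):
            tpd = float(np.hypot(x - motor[0], y - motor[1]))
            out.append(
                Touchpoint(
                    t_tp=float(t[p]), TPT=float(w / rate), TPF=float(combined[p]),
                    x_tp=float(x), y_tp=float(y), TPD=tpd,
                )
            )
        else:
            out.append(
                Touchpoint(t_tp=float(t[p]), TPT=float(w / rate), TPF=float(combined[p]))
            )
    return out


def compute_velocity_projection(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    motor,
    smooth_samples: int = 5,
) -> ProjectionSeries:
    """Project fingertip velocity onto the direction toward the motor.

    Positions are smoothed with a centered ``smooth_samples``-sample moving
    average, differentiated by central differences, and each frame's
    velocity is dotted with the unit vector from the (smoothed) fingertip
    position to the motor. Frames adjacent to missing positions are NaN.
    Requires at least 3 valid frames.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    motor = np.asarray(motor, float)
    valid = np.isfinite(x) & np.isfinite(y)
    if valid.sum() < 3 or len(t) < 3:
        raise TooFewFrames(f"{int(valid.sum())} valid frames; need >= 3")

    k = smooth_samples
    kernel = np.ones(k) / k
    # NaN-aware moving average: frames whose kernel support touches a gap are NaN
    xf = np.where(valid, x, 0.0)
    yf = np.where(valid, y, 0.0)
    wsum = np.convolve(valid.astype(float), kernel, mode="same")
    xs = np.convolve(xf, kernel, mode="same") / np.where(wsum > 0, wsum, np.nan)
    ys = np.convolve(yf, kernel, mode="same") / np.where(wsum > 0, wsum, np.nan)
    full = np.convolve(valid.astype(float), kernel, mode="same") > 1 - 1e-9
    xs[~full] = np.nan
    ys[~full] = np.nan

    vp = np.full(len(t), np.nan)
    dt2 = t[2:] - t[:-2]
    vx = (xs[2:] - xs[:-2]) / dt2
    vy = (ys[2:] - ys[:-2]) / dt2
    ux = motor[0] - xs[1:-1]
    uy = motor[1] - ys[1:-1]
    norm = np.hypot(ux, uy)
    with np.errstate(invalid="ignore", divide="ignore"):
        vp[1:-1] = (vx * ux + vy * uy) / norm
    vp[1:-1][norm == 0] = np.nan
    return ProjectionSeries(t=t, V_p=vp)


def compute_rcm(proj: ProjectionSeries, cfg: PeakConfig = PeakConfig()) -> float | None:
    """Ratio of correct movement: % of significant velocity projections toward the motor.

    Significant means |V_p| above the 20 mm/s threshold; returns None
    (undefined) when no frame is significant.
    """
    v = proj.V_p[np.isfinite(proj.V_p)]
    thr = cfg.rcm_speed_threshold
    denom = int(np.sum(np.abs(v) > thr))
    if denom == 0:
        return None
    return 100.0 * int(np.sum(v > thr)) / denom


def compute_rntp(
    touchpoints: list[Touchpoint], cfg: PeakConfig = PeakConfig()
) -> float | None:
    """Ratio of near touchpoints: % of located touchpoints strictly within 40 mm.

    None (undefined) when no touchpoint has a valid location.
    """
    located = [tp for tp in touchpoints if tp.located]
    if not located:
        return None
    near = sum(1 for tp in located if tp.TPD < cfg.rntp_radius)
    return 100.0 * near / len(located)


def compute_trial_metrics(
    bundle: TrialBundle,
    window: PalpationWindow,
    touchpoints: list[Touchpoint],
    layout: SimulatorLayout,
    cfg: PeakConfig = PeakConfig(),
) -> TrialMetrics:
    """Assemble the twelve per-trial metrics from detected touchpoints.

    Dwell + idle exactly partitions the window. Path length sums planar
    segment lengths over consecutive valid fingertip frames (raw positions;
    smoothing is applied only for the velocity projection feeding RCM).
    """
    sl = _window_slice(bundle, window)
    f_ind, f_mid, fx, fy = bundle.require(
        "force_index", "force_middle", "finger_x", "finger_y"
    )
    t = f_ind.t[sl]
    combined = f_ind.v[sl] + f_mid.v[sl]
    x, y = fx.v[sl], fy.v[sl]
    W = window.T_end - window.T_start

    n = len(touchpoints)
    dwell = float(sum(tp.TPT for tp in touchpoints))
    total_force = float(sum(tp.TPT * tp.TPF for tp in touchpoints))
    finite = combined[np.isfinite(combined)]
    force_range = float(np.max(finite) - np.min(finite)) if finite.size else np.nan

    valid = np.isfinite(x) & np.isfinite(y)
    pair = valid[:-1] & valid[1:]
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))[pair])) if len(x) > 1 else 0.0

    rcm: float | None
    try:
        proj = compute_velocity_projection(t, x, y, layout.motor(bundle.fistula_id))
        rcm = compute_rcm(proj, cfg)
    except TooFewFrames:
        rcm = None
    rntp = compute_rntp(touchpoints, cfg)

    located = [tp for tp in touchpoints if tp.located]
    mean_tpd = float(np.mean([tp.TPD for tp in located])) if located else None

    return TrialMetrics(
        touchpoints=n,
        frequency=n / W,
        total_force=total_force,
        force_range=force_range,
        dwell_time=dwell,
        idle_time=W - dwell,
        path_length=path,
        rcm=rcm,
        rntp=rntp,
        mean_tpt=float(np.mean([tp.TPT for tp in touchpoints])) if n else np.nan,
        mean_tpf=float(np.mean([tp.TPF for tp in touchpoints])) if n else np.nan,
        mean_tpd=mean_tpd,
        location_valid=bool(valid.all()),
    )
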