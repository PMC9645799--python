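"""Isolating the palpation window [T_start, T_end] from a trial recording.

A typical trial begins with the hand at rest (quiescent forces), followed by
a train of fingertip presses while the subject searches for the fistula, and
ends when the subject grips the needle for insertion — seen as a thumb-force
change coinciding with needle-tip movement.

``T_start`` is the first time the smoothed index- or middle-finger force
rises by at least ``start_force_delta`` above its level at the end of a
quiescent period (>= ``quiescence_window`` seconds during which both
channels vary by less than ``start_force_delta`` peak-to-peak).

``T_end`` is the first time after ``T_start`` at which the thumb force has
changed by at least ``thumb_force_delta`` within the trailing coincidence
window AND the needle tip has displaced by at least
``needle_disp_threshold`` mm within the centered coincidence window — the
conjunction distinguishes needle pickup from incidental needle drift or
thumb contact alone.

Trials where no qualifying start (or end) exists get status ``no_start``
(``no_end``) and are excluded from metrics; a manually annotated window
(from video review) overrides automatic detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .bundles import TrialBundle
from .errors import NotResampled

__all__ = ["SegmentationConfig", "PalpationWindow", "detect_palpation_window"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the window-detection algorithm (all must be positive)."""

    quiescence_window: float = 1.0  # s of "no change in force" before the start
    start_force_delta: float = 0.10  # N rise marking the first press
    thumb_force_delta: float = 0.15  # N thumb change marking needle grip
    needle_disp_threshold: float = 5.0  # mm needle movement confirming pickup
    coincidence_window: float = 0.5  # s window tying thumb change to needle motion
    smoothing_window: float = 0.05  # s centered moving average applied to forces

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if not (getattr(self, f) > 0):
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class PalpationWindow:
    """Detected (or manually annotated) palpation interval."""

    T_start: float
    T_end: float
    method: str  # "auto" | "manual"
    status: str  # "ok" | "no_start" | "no_end" | "manual_needed"

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def duration(self) -> float:
        return self.T_end - self.T_start


def _smooth(x: np.ndarray, window_s: float, rate: float) -> np.ndarray:
    size = max(1, int(round(window_s * rate)))
    if size % 2 == 0:
        size += 1
    return uniform_filter1d(x, size=size, mode="nearest")


def _trailing_ptp(x: np.ndarray, size: int) -> np.ndarray:
    """Peak-to-peak of x over the trailing window [i-size+1, i]."""
    # positive origin shifts the filter window left: output[i] covers [i-size+1, i]
    shift = (size - 1) // 2
    hi = maximum_filter1d(x, size=size, mode="nearest", origin=shift)
    lo = minimum_filter1d(x, size=size, mode="nearest", origin=shift)
    return hi - lo


def detect_palpation_window(
    bundle: TrialBundle, cfg: SegmentationConfig = SegmentationConfig()
) -> PalpationWindow:
    """Detect the palpation window on a grid-resampled trial.

    Requires force_index, force_middle, force_thumb and the three needle
    channels; the bundle must have been passed through
    :func:`palpmetrics.bundles.resample_to_grid`. A manual window in the
    bundle metadata is returned verbatim with ``method="manual"``.
    """
    if bundle.grid_rate is None:
        raise NotResampled(f"trial {bundle.trial_id}: resample_to_grid first")
    if bundle.manual_window is not None:
        a, b = bundle.manual_window
        return PalpationWindow(a, b, method="manual", status="ok")

    rate = bundle.grid_rate
    f_ind, f_mid, f_thb, nx, ny, nz = (
        c.v
        for c in bundle.require(
            "force_index", "force_middle", "force_thumb",
            "needle_x", "needle_y", "needle_z",
        )
    )
    t = bundle.channels["force_index"].t
    n = len(t)

    fi = _smooth(np.nan_to_num(f_ind), cfg.smoothing_window, rate)
    fm = _smooth(np.nan_to_num(f_mid), cfg.smoothing_window, rate)
    ft = _smooth(np.nan_to_num(f_thb), cfg.smoothing_window, rate)

    q = max(2, int(round(cfg.quiescence_window * rate)) + 1)
    if n <= q:
        return PalpationWindow(np.nan, np.nan, "auto", "no_start")

    quiet = (_trailing_ptp(fi, q) < cfg.start_force_delta) & (
        _trailing_ptp(fm, q) < cfg.start_force_delta
    )
    quiet[: q - 1] = False  # trailing window not yet fully inside the trial

    # for each sample, index of the most recent quiescent sample (or -1)
    idx = np.where(quiet, np.arange(n), -1)
    last_quiet = np.maximum.accumulate(idx)
    valid = last_quiet >= 0
    # baseline = minimum over the quiescent window, so a pulse already rising
    # inside a still-quiescent window does not inflate its own reference level
    shift = (q - 1) // 2
    min_i = minimum_filter1d(fi, size=q, mode="nearest", origin=shift)
    min_m = minimum_filter1d(fm, size=q, mode="nearest", origin=shift)
    base_i = min_i[np.clip(last_quiet, 0, n - 1)]
    base_m = min_m[np.clip(last_quiet, 0, n - 1)]
    rise = valid & ((fi - base_i >= cfg.start_force_delta) | (fm - base_m >= cfg.start_force_delta))
    starts = np.flatnonzero(rise)
    if starts.size == 0:
        return PalpationWindow(np.nan, np.nan, "auto", "no_start")
    i_start = int(starts[0])

    c = max(1, int(round(cfg.coincidence_window * rate)))
    thumb_change = _trailing_ptp(ft, c + 1) >= cfg.thumb_force_delta
    # centered-window needle displacement, per-axis ptp combined in quadrature
    size = 2 * c + 1
    disp2 = np.zeros(n)
    for axis in (nx, ny, nz):
        a = np.nan_to_num(axis)
        ptp = maximum_filter1d(a, size=size, mode="nearest") - minimum_filter1d(
            a, size=size, mode="nearest"
        )
        disp2 += ptp**2
    needle_moves = np.sqrt(disp2) >= cfg.needle_disp_threshold

    ends = np.flatnonzero(thumb_change & needle_moves)
    ends = ends[ends > i_start]
    if ends.size == 0:
        return PalpationWindow(float(t[i_start]), np.nan, "auto", "no_end")
    i_end = int(ends[0])
    return PalpationWindow(float(t[i_start]), float(t[i_end]), "auto", "ok")
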