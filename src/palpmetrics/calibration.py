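"""Simulator layout: fistula axes and anastomosis-motor locations.

Before data collection the simulator is calibrated by tracing a finger along
each fistula's central axis while recording fingertip position; the traces
are fitted to lines in the bed plane. The vibration-motor (anastomosis)
location of each fistula is part of the layout and is the reference point
for every location metric (distance to motor, ratio of correct movement,
ratio of near touchpoints). Axis fits use orthogonal (total) least squares:
the line minimizing the summed squared perpendicular distances, which is the
first principal component of the centered point cloud.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInput, IsotropicCloud, SchemaError

LAYOUT_SCHEMA_VERSION = 1

#: minimum principal-axis ratio for a well-posed axis fit
MIN_AXIS_RATIO = 1.05


@dataclass(frozen=True)
class FistulaAxis:
    """A fitted central axis: anchor point + unit direction, bed plane, mm."""

    anchor: tuple[float, float]
    direction: tuple[float, float]
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        n = math.hypot(*self.direction)
        if abs(n - 1.0) > 1e-9:
            raise SchemaError(f"axis direction must be unit norm, |d| = {n}")


@dataclass(frozen=True)
class Fistula:
    """One fistula: its central axis and the location of its vibration motor."""

    axis: FistulaAxis
    motor: tuple[float, float]  # (x_m, y_m), mm, bed frame

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.motor):
            raise SchemaError("motor location must be finite")


@dataclass(frozen=True)
class SimulatorLayout:
    """The four fistulas plus the circular bed radius (mm)."""

    fistulas: dict[int, Fistula]
    bed_radius: float

    def __post_init__(self) -> None:
        if sorted(self.fistulas) != [1, 2, 3, 4]:
            raise SchemaError("layout must define fistulas 1..4")
        if not (self.bed_radius > 0):
            raise SchemaError("bed_radius must be positive")

    def motor(self, fistula_id: int) -> np.ndarray:
        return np.asarray(self.fistulas[fistula_id].motor, dtype=float)


def fit_fistula_axis(points) -> FistulaAxis:
    """Fit a fistula central axis to traced fingertip points by total least squares.

    ``points`` is an (n, 2) array-like of bed-plane coordinates in mm (any z
    component must be projected out beforehand). Returns the orthogonal
    least-squares line with the RMS perpendicular residual; the direction
    sign is chosen so the component along the coordinate axis of larger
    point spread is positive.

    Raises :class:`DegenerateInput` for fewer than two distinct points and
    :class:`IsotropicCloud` when the principal-axis ratio is below 1.05
    (no dominant direction).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateInput("points must be an (n, 2) array")
    pts = pts[np.isfinite(pts).all(axis=1)]
    distinct = np.unique(pts, axis=0)
    if len(distinct) < 2:
        raise DegenerateInput("need at least 2 distinct points")

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(pts) > 2 and s[1] > 0 and s[0] / s[1] < MIN_AXIS_RATIO:
        raise IsotropicCloud(
            f"principal-axis ratio {s[0] / s[1]:.3f} < {MIN_AXIS_RATIO}"
        )
    direction = vt[0]
    spread = np.ptp(pts, axis=0)
    major = int(np.argmax(spread))
    if direction[major] < 0:
        direction = -direction
    rms = float(s[1] / math.sqrt(len(pts))) if len(s) > 1 else 0.0
    return FistulaAxis(
        anchor=(float(centroid[0]), float(centroid[1])),
        direction=(float(direction[0]), float(direction[1])),
        rms_residual=rms,
    )


def default_layout(bed_radius: float = 150.0, motor_radius: float = 80.0) -> SimulatorLayout:
    """Nominal layout: four fistulas placed radially at 45/135/225/315 degrees.

    Each axis runs radially through its motor. Used by the synthetic cohort
    generator and as a sensible starting layout for the real device.
    """
    fistulas = {}
    for fid, deg in zip((1, 2, 3, 4), (45.0, 135.0, 225.0, 315.0)):
        a = math.radians(deg)
        d = (math.cos(a), math.sin(a))
        motor = (motor_radius * d[0], motor_radius * d[1])
        fistulas[fid] = Fistula(axis=FistulaAxis(anchor=motor, direction=d), motor=motor)
    return SimulatorLayout(fistulas=fistulas, bed_radius=bed_radius)


def save_layout(layout: SimulatorLayout, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "schema_version": LAYOUT_SCHEMA_VERSION,
        "bed_radius": layout.bed_radius,
        "fistulas": {
            str(fid): {
                "anchor": list(f.axis.anchor),
                "direction": list(f.axis.direction),
                "rms_residual": f.axis.rms_residual,
                "motor": list(f.motor),
            }
            for fid, f in sorted(layout.fistulas.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_layout(path: str | Path) -> SimulatorLayout:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    try:
        fistulas = {
            int(fid): Fistula(
                axis=FistulaAxis(
                    anchor=tuple(f["anchor"]),
                    direction=tuple(f["direction"]),
                    rms_residual=float(f.get("rms_residual", 0.0)),
                ),
                motor=tuple(f["motor"]),
            )
            for fid, f in doc["fistulas"].items()
        }
        return SimulatorLayout(fistulas=fistulas, bed_radius=float(doc["bed_radius"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed layout: {exc}") from exc
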