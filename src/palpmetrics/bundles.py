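"""Trial bundles: the on-disk and in-memory data model for one cannulation trial.

A trial bundle holds the synchronized multimodal recordings of a single
palpation + cannulation attempt on the simulator: three fingertip force
channels (thumb / index / middle, in newtons), fingertip position and
needle-tip position (mm, simulator-bed frame, origin at bed center, x-y the
bed plane), a binary blood-flashback channel, plus trial metadata (subject,
fistula 1-4, skin thickness, motor vibration intensity, GRS expert ratings
and the stable-flashback outcome flag ``stb``).

On disk a bundle is a directory containing ``metadata.json`` and one
``<channel>.csv`` per channel with header ``t,v`` (RFC-4180, UTF-8,
'.' decimal separator, timestamps in seconds from trial start). Floats are
written with 17 significant digits so write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    EmptyOverlap,
    MissingChannel,
    NonMonotoneTime,
    RangeError,
    SchemaError,
)

SCHEMA_VERSION = 1

#: channels every complete trial must carry
REQUIRED_CHANNELS = (
    "force_thumb",
    "force_index",
    "force_middle",
    "finger_x",
    "finger_y",
    "finger_z",
    "needle_x",
    "needle_y",
    "needle_z",
    "flashback",
)

#: channels resampled by previous-value hold instead of linear interpolation
STEP_CHANNELS = frozenset({"flashback"})

DEFAULT_GAP_MAX = 0.1  # s; source gaps longer than this become missing samples


class SkillGroup(str, enum.Enum):
    """Expert-rated performance tier used throughout the analysis."""

    HP = "HP"
    MP = "MP"
    LP = "LP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ChannelSeries:
    """One sensor stream: values ``v`` sampled at strictly increasing times ``t``."""

    name: str
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1 or len(self.t) != len(self.v):
            raise SchemaError(
                f"channel {self.name!r}: t and v must be 1-D and equal length"
            )
        if np.isnan(self.t).any():
            raise NonMonotoneTime(f"channel {self.name!r}: NaN timestamps")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise NonMonotoneTime(
                f"channel {self.name!r}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrialBundle:
    """All channels and metadata of one trial."""

    trial_id: str
    subject_id: str
    fistula_id: int
    skin: str  # "thin" | "thick"
    vibration: str  # "low" | "high"
    grs_palpation: int
    grs_overall: int
    stb: int
    channels: dict[str, ChannelSeries]
    manual_window: tuple[float, float] | None = None
    grid_rate: float | None = None  # Hz; set once resampled to a common grid
    extras: dict = field(default_factory=dict)  # unknown metadata keys, preserved

    def __post_init__(self) -> None:
        if self.fistula_id not in (1, 2, 3, 4):
            raise SchemaError(f"fistula_id must be 1..4, got {self.fistula_id}")
        if self.skin not in ("thin", "thick"):
            raise SchemaError(f"skin must be thin|thick, got {self.skin!r}")
        if self.vibration not in ("low", "high"):
            raise SchemaError(f"vibration must be low|high, got {self.vibration!r}")
        for name in ("grs_palpation", "grs_overall"):
            s = getattr(self, name)
            if not (isinstance(s, int) and 1 <= s <= 7):
                raise RangeError(f"{name} must be an integer in 1..7, got {s!r}")
        if self.stb not in (0, 1):
            raise SchemaError(f"stb must be 0 or 1, got {self.stb!r}")
        if self.manual_window is not None:
            a, b = self.manual_window
            if not (math.isfinite(a) and math.isfinite(b) and a < b):
                raise SchemaError(f"manual_window must satisfy a < b, got {a}, {b}")

    @property
    def complete(self) -> bool:
        return all(c in self.channels for c in REQUIRED_CHANNELS)

    def require(self, *names: str) -> list[ChannelSeries]:
        out = []
        for n in names:
            if n not in self.channels:
                raise MissingChannel(f"trial {self.trial_id}: channel {n!r} missing")
            out.append(self.channels[n])
        return out

    @property
    def duration(self) -> float:
        t0 = min(c.t[0] for c in self.channels.values())
        t1 = max(c.t[-1] for c in self.channels.values())
        return t1 - t0

    def metadata_dict(self) -> dict:
        md = {
            "schema_version": SCHEMA_VERSION,
            "trial_id": self.trial_id,
            "subject_id": self.subject_id,
            "fistula_id": self.fistula_id,
            "skin": self.skin,
            "vibration": self.vibration,
            "grs_palpation": self.grs_palpation,
            "grs_overall": self.grs_overall,
            "stb": self.stb,
            "manual_window": list(self.manual_window) if self.manual_window else None,
        }
        md.update(self.extras)
        return md


def classify_skill(grs_palpation: int, grs_overall: int) -> SkillGroup:
    """Assign the HP / MP / LP performance tier from the two GRS ratings.

    High performers scored 7 in both palpation and overall skill; low
    performers scored <= 5 in palpation and <= 4 overall; everyone else is
    a mid performer. The two rules are disjoint, so every valid score pair
    maps to exactly one group.
    """
    for name, s in (("grs_palpation", grs_palpation), ("grs_overall", grs_overall)):
        if not (isinstance(s, (int, np.integer)) and 1 <= s <= 7):
            raise RangeError(f"{name} must be an integer in 1..7, got {s!r}")
    if grs_palpation == 7 and grs_overall == 7:
        return SkillGroup.HP
    if grs_palpation <= 5 and grs_overall <= 4:
        return SkillGroup.LP
    return SkillGroup.MP


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

_META_REQUIRED = {
    "trial_id": str,
    "subject_id": str,
    "fistula_id": int,
    "skin": str,
    "vibration": str,
    "grs_palpation": int,
    "grs_overall": int,
    "stb": int,
}


def write_trial_bundle(bundle: TrialBundle, path: str | Path) -> Path:
    """Write a bundle as a directory of metadata.json + per-channel CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.metadata_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    for name, ch in bundle.channels.items():
        with open(path / f"{name}.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("t,v\n")
            for t, v in zip(ch.t, ch.v):
                fh.write(f"{t:.17g},{v:.17g}\n")
    return path


def read_trial_bundle(path: str | Path) -> TrialBundle:
    """Read a bundle directory written by :func:`write_trial_bundle`.

    Raises :class:`MissingChannel` when a required channel file is absent,
    :class:`SchemaError` on invalid metadata, :class:`NonMonotoneTime` on
    out-of-order timestamps.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError(f"{meta_path} not found")
    with open(meta_path, encoding="utf-8") as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{meta_path}: invalid JSON: {exc}") from exc
    for key, typ in _META_REQUIRED.items():
        if key not in meta:
            raise SchemaError(f"{meta_path}: missing key {key!r}")
        if not isinstance(meta[key], typ):
            raise SchemaError(f"{meta_path}: key {key!r} must be {typ.__name__}")

    channels: dict[str, ChannelSeries] = {}
    for name in REQUIRED_CHANNELS:
        f = path / f"{name}.csv"
        if not f.exists():
            raise MissingChannel(f"{f} absent")
        channels[name] = _read_channel_csv(name, f)
    # pick up any extra channel CSVs beyond the required set
    for f in sorted(path.glob("*.csv")):
        name = f.stem
        if name not in channels:
            channels[name] = _read_channel_csv(name, f)

    mw = meta.get("manual_window")
    extras = {
        k: v
        for k, v in meta.items()
        if k not in _META_REQUIRED and k not in ("manual_window", "schema_version")
    }
    return TrialBundle(
        trial_id=meta["trial_id"],
        subject_id=meta["subject_id"],
        fistula_id=meta["fistula_id"],
        skin=meta["skin"],
        vibration=meta["vibration"],
        grs_palpation=meta["grs_palpation"],
        grs_overall=meta["grs_overall"],
        stb=meta["stb"],
        channels=channels,
        manual_window=tuple(mw) if mw else None,
        extras=extras,
    )


def _read_channel_csv(name: str, f: Path) -> ChannelSeries:
    data = np.genfromtxt(f, delimiter=",", skip_header=1, dtype=float)
    data = np.atleast_2d(data)
    if data.size == 0:
        raise SchemaError(f"{f}: empty channel")
    if data.shape[1] != 2:
        raise SchemaError(f"{f}: expected two columns t,v")
    return ChannelSeries(name, data[:, 0], data[:, 1])


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_to_grid(
    bundle: TrialBundle, rate: float, gap_max: float = DEFAULT_GAP_MAX
) -> TrialBundle:
    """Resample every channel onto one uniform grid at ``rate`` Hz.

    The grid spans the intersection of the channel time ranges. Continuous
    channels are linearly interpolated; grid points falling strictly inside a
    source gap longer than ``gap_max`` seconds become NaN (missing) rather
    than being bridged. The flashback channel is resampled by
    previous-value hold. The operation is idempotent at a fixed rate.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    for ch in bundle.channels.values():
        if len(ch) < 2:
            raise SchemaError(f"channel {ch.name!r} has < 2 samples")
    t0 = max(ch.t[0] for ch in bundle.channels.values())
    t1 = min(ch.t[-1] for ch in bundle.channels.values())
    if t1 <= t0:
        raise EmptyOverlap(f"trial {bundle.trial_id}: channel ranges do not intersect")
    n = int(math.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate

    out: dict[str, ChannelSeries] = {}
    for name, ch in bundle.channels.items():
        if name in STEP_CHANNELS:
            idx = np.searchsorted(ch.t, grid + 1e-12, side="right") - 1
            idx = np.clip(idx, 0, len(ch.t) - 1)
            v = ch.v[idx]
        else:
            v = np.interp(grid, ch.t, ch.v)
            v = _mask_gaps(grid, ch, v, gap_max)
        out[name] = ChannelSeries(name, grid, v)
    return replace(bundle, channels=out, grid_rate=float(rate))


def _mask_gaps(
    grid: np.ndarray, ch: ChannelSeries, v: np.ndarray, gap_max: float
) -> np.ndarray:
    """NaN-out grid samples interpolated across long source gaps or NaN values."""
    dt = np.diff(ch.t)
    left = np.searchsorted(ch.t, grid, side="right") - 1
    left = np.clip(left, 0, len(ch.t) - 2)
    eps = 1e-9
    interior = (grid > ch.t[left] + eps) & (grid < ch.t[left + 1] - eps)
    bad_interval = dt[left] > gap_max
    nan_src = np.isnan(ch.v)
    bad_value = nan_src[left] | (nan_src[left + 1] & interior)
    # grid points coinciding with the right endpoint take that sample's validity
    right_hit = np.isclose(grid, ch.t[left + 1])
    bad_value = np.where(right_hit, nan_src[left + 1], bad_value)
    v = v.copy()
    v[(interior & bad_interval) | bad_value] = np.nan
    return v
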