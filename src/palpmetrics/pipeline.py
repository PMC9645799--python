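"""End-to-end convenience layer: resample -> segment -> metrics -> stats.

These helpers run the full analysis on in-memory bundles (as produced by
:mod:`palpmetrics.synthetic` or read from disk) and return tidy pandas
frames; the CLI is a thin wrapper over them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bundles import TrialBundle, classify_skill, read_trial_bundle, resample_to_grid
from .calibration import SimulatorLayout, default_layout
from .errors import EmptyWindow, PalpError
from .metrics import (
    METRIC_NAMES,
    PeakConfig,
    compute_trial_metrics,
    detect_touchpoints,
)
from .segmentation import PalpationWindow, SegmentationConfig, detect_palpation_window

__all__ = ["DEFAULT_RATE", "load_cohort", "segment_cohort", "metrics_table"]

DEFAULT_RATE = 100.0  # Hz common grid


def load_cohort(cohort_dir: str | Path) -> list[TrialBundle]:
    """Read every trial bundle listed in a cohort directory's cohort.json."""
    import json

    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "cohort.json", encoding="utf-8") as fh:
        index = json.load(fh)
    return [read_trial_bundle(cohort_dir / tid) for tid in index["trials"]]


def segment_cohort(
    bundles: list[TrialBundle],
    cfg: SegmentationConfig = SegmentationConfig(),
    rate: float = DEFAULT_RATE,
) -> pd.DataFrame:
    """Detect palpation windows for every trial; one row per trial."""
    rows = []
    for b in bundles:
        rb = resample_to_grid(b, rate)
        w = detect_palpation_window(rb, cfg)
        rows.append(
            {
                "trial_id": b.trial_id,
                "T_start": w.T_start,
                "T_end": w.T_end,
                "method": w.method,
                "status": w.status,
            }
        )
    return pd.DataFrame(rows)


def metrics_table(
    bundles: list[TrialBundle],
    layout: SimulatorLayout | None = None,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    peak_cfg: PeakConfig = PeakConfig(),
    rate: float = DEFAULT_RATE,
    segments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-trial metric table with skill group and outcome.

    Trials that fail segmentation keep their identity columns with status
    set and NaN metrics; downstream statistics drop them. When ``segments``
    is given (e.g. from the CLI's segment stage, possibly containing manual
    windows), its T_start/T_end/status are used instead of re-detection.
    """
    layout = layout or default_layout()
    seg_idx = None
    if segments is not None:
        seg_idx = segments.set_index("trial_id")
    rows = []
    for b in bundles:
        rb = resample_to_grid(b, rate)
        if seg_idx is not None and b.trial_id in seg_idx.index:
            s = seg_idx.loc[b.trial_id]
            w = PalpationWindow(
                float(s["T_start"]), float(s["T_end"]), str(s["method"]), str(s["status"])
            )
        else:
            w = detect_palpation_window(rb, seg_cfg)
        row = {
            "trial_id": b.trial_id,
            "subject_id": b.subject_id,
            "group": classify_skill(b.grs_palpation, b.grs_overall).value,
            "fistula_id": b.fistula_id,
            "skin": b.skin,
            "vibration": b.vibration,
            "stb": b.stb,
            "T_start": w.T_start,
            "T_end": w.T_end,
            "seg_method": w.method,
            "seg_status": w.status,
            "location_valid": False,
        }
        row.update({m: np.nan for m in METRIC_NAMES})
        if w.ok:
            try:
                tps = detect_touchpoints(rb, w, layout, peak_cfg)
                tm = compute_trial_metrics(rb, w, tps, layout, peak_cfg)
                d = tm.as_dict()
                row.update(
                    {m: (np.nan if d[m] is None else d[m]) for m in METRIC_NAMES}
                )
                row["location_valid"] = d["location_valid"]
            except (EmptyWindow, PalpError):
                row["seg_status"] = "manual_needed"
        rows.append(row)
    return pd.DataFrame(rows)
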