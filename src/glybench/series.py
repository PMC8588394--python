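"""CGM data model: patient series, gap imputation, scaling, windowing, I/O.

A patient record is a uniform 5-minute grid carrying four channels: blood
glucose (mg/dL, gaps allowed as NaN), basal insulin rate, insulin boluses,
and carbohydrate intake. Preprocessing fills glucose gaps with a cubic
spline, scales glucose by 0.01 and min-max normalizes the other channels
using training-partition statistics, and cuts supervised windows of 25
steps (120 min of history plus the current step) with targets 30/60/120
minutes ahead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import (
    ExtrapolationError,
    InvalidPredictionError,
    InvalidStatsError,
    UnfillableSeriesError,
)

__all__ = [
    "SAMPLE_MINUTES",
    "HISTORY_STEPS",
    "BG_MIN",
    "BG_MAX",
    "BG_SCALE",
    "CHANNELS",
    "PatientSeries",
    "ScalingStats",
    "WindowedDataset",
    "fill_gaps",
    "compute_scaling_stats",
    "scale_features",
    "unscale_bg",
    "make_windows",
    "clip_predictions",
    "read_series_csv",
    "write_series_csv",
]

SAMPLE_MINUTES = 5
HISTORY_STEPS = 25  # 24 history steps + the current one
BG_MIN, BG_MAX = 40.0, 400.0  # CGM hardware range, mg/dL
BG_SCALE = 0.01
CHANNELS = ("bg", "bas", "bol", "ch")
DEFAULT_HORIZONS = (30, 60, 120)


@dataclass
class PatientSeries:
    """One patient's multichannel series on a strict 5-minute grid.

    ``split`` labels each step "train" or "test"; the test block is the
    tail of the record. ``bg`` may contain NaN (sensor dropouts); the
    event channels encode absence as 0.
    """

    patient_id: str
    timestamps: np.ndarray  # minutes, strictly increasing, 5-min spacing
    bg: np.ndarray
    bas: np.ndarray
    bol: np.ndarray
    ch: np.ndarray
    split: np.ndarray  # array of "train"/"test"
    long_gap_flags: np.ndarray | None = field(default=None, repr=False)
    scaled: bool = False  # True once scale_features has been applied

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.split = np.asarray(self.split, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if any(len(getattr(self, c)) != n for c in CHANNELS) or len(self.split) != n:
            raise ValueError("channel length mismatch")
        dt = np.diff(self.timestamps)
        if n > 1 and not np.allclose(dt, SAMPLE_MINUTES):
            raise ValueError("timestamps must be a uniform 5-min grid")
        present = ~np.isnan(self.bg)
        if not self.scaled:
            if np.any(self.bg[present] < BG_MIN) or np.any(self.bg[present] > BG_MAX):
                raise ValueError(f"bg outside [{BG_MIN}, {BG_MAX}] mg/dL")
            for name in ("bas", "bol", "ch"):
                if np.any(getattr(self, name) < 0):
                    raise ValueError(f"{name} must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.bg).sum())

    def partition_index(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.split == which)


@dataclass(frozen=True)
class ScalingStats:
    """Per-channel min/max fitted on the training partition only."""

    minmax: dict  # channel -> (min, max) for bas/bol/ch

    @classmethod
    def from_series(cls, series: PatientSeries) -> "ScalingStats":
        train = series.partition_index("train")
        mm = {}
        for name in ("bas", "bol", "ch"):
            x = getattr(series, name)[train]
            mm[name] = (float(np.min(x)), float(np.max(x)))
        return cls(minmax=mm)


def compute_scaling_stats(series: PatientSeries) -> ScalingStats:
    return ScalingStats.from_series(series)


@dataclass
class WindowedDataset:
    """Supervised samples: (n, 25, 4) scaled inputs and per-horizon targets.

    Targets are scaled glucose values ``horizon`` minutes after each
    window's final step. Windows never cross the train/test boundary.
    """

    inputs: np.ndarray  # (n, 25, 4)
    targets: dict  # horizon minutes -> (n,) scaled bg
    horizons: tuple

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def horizon_steps(self) -> dict:
        return {h: h // SAMPLE_MINUTES for h in self.horizons}


def fill_gaps(series: PatientSeries, long_gap_minutes: float = 60.0) -> PatientSeries:
    """Complete missing glucose samples with a cubic spline.

    The spline interpolates through the observed (time, bg) points
    (not-a-knot boundary) and filled values are clipped to the CGM range.
    Gaps longer than ``long_gap_minutes`` are still filled but flagged in
    ``long_gap_flags``. Interpolation only: a missing first or last sample
    raises :class:`ExtrapolationError`.
    """
    present = ~np.isnan(series.bg)
    if present.sum() < 4:
        raise UnfillableSeriesError(
            f"patient {series.patient_id}: {int(present.sum())} glucose anchors, need >= 4"
        )
    if not present[0] or not present[-1]:
        raise ExtrapolationError(
            f"patient {series.patient_id}: leading/trailing gap cannot be interpolated"
        )
    if present.all():
        return series
    t, y = series.timestamps[present], series.bg[present]
    spline = CubicSpline(t, y, bc_type="not-a-knot")
    bg = series.bg.copy()
    missing = ~present
    bg[missing] = np.clip(spline(series.timestamps[missing]), BG_MIN, BG_MAX)

    flags = np.zeros(len(series), dtype=bool)
    max_steps = int(long_gap_minutes / SAMPLE_MINUTES)
    # flag contiguous filled runs longer than the threshold
    idx = np.flatnonzero(missing)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            if len(run) > max_steps:
                flags[run] = True
    return replace(series, bg=bg, long_gap_flags=flags)


def scale_features(
    series: PatientSeries,
    stats: ScalingStats,
    normalize_bg: bool = False,
) -> PatientSeries:
    """Scale channels for training: bg x 0.01, events min-max to [0, 1].

    Constant channels (max == min on the training partition) map to zero.
    ``normalize_bg=True`` additionally min-max normalizes the scaled bg
    channel (exposed as a switch; off by default).
    """
    scaled = {"bg": series.bg * BG_SCALE}
    if normalize_bg:
        lo, hi = BG_MIN * BG_SCALE, BG_MAX * BG_SCALE
        scaled["bg"] = (scaled["bg"] - lo) / (hi - lo)
    for name in ("bas", "bol", "ch"):
        lo, hi = stats.minmax[name]
        if hi < lo:
            raise InvalidStatsError(f"{name}: max {hi} < min {lo}")
        x = getattr(series, name)
        scaled[name] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return replace(series, scaled=True, **scaled)


def unscale_bg(values: np.ndarray) -> np.ndarray:
    """Map model-scale glucose back to mg/dL (inverse of the 0.01 factor)."""
    return np.asarray(values, dtype=float) / BG_SCALE


def make_windows(
    series: PatientSeries,
    horizons=DEFAULT_HORIZONS,
    partition: str = "train",
) -> WindowedDataset:
    """Cut supervised windows from one partition of a scaled series.

    A window ending at step t yields input ``[t-24 .. t]`` (25 steps, 4
    channels) and, per horizon, the glucose ``h`` minutes after t. Both
    the history and the farthest target must lie inside the partition, so
    a partition of length L yields ``L - 24 - max(horizon_steps)`` samples.
    """
    horizons = tuple(sorted(horizons))
    steps = {h: h // SAMPLE_MINUTES for h in horizons}
    idx = series.partition_index(partition)
    if idx.size and not np.all(np.diff(idx) == 1):
        raise ValueError("partition must be contiguous")
    length = idx.size
    max_ahead = max(steps.values())
    n = length - (HISTORY_STEPS - 1) - max_ahead
    if n <= 0:
        warnings.warn(
            f"partition '{partition}' too short for windowing "
            f"(L={length} < {HISTORY_STEPS + max_ahead})",
            stacklevel=2,
        )
        return WindowedDataset(
            inputs=np.empty((0, HISTORY_STEPS, 4)),
            targets={h: np.empty(0) for h in horizons},
            horizons=horizons,
        )
    x = np.stack([getattr(series, c)[idx] for c in CHANNELS], axis=-1)
    ends = np.arange(HISTORY_STEPS - 1, HISTORY_STEPS - 1 + n)
    windows = np.stack([x[e - HISTORY_STEPS + 1 : e + 1] for e in ends])
    bg = x[:, 0]
    targets = {h: bg[ends + s] for h, s in steps.items()}
    return WindowedDataset(inputs=windows, targets=targets, horizons=horizons)


def clip_predictions(values: np.ndarray, model_id: str = "model") -> np.ndarray:
    """Bound predictions to the 40-400 mg/dL CGM range.

    Applied to every model output after rescaling to mg/dL and before any
    metric. Non-finite values indicate a diverged model and are refused.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidPredictionError(f"{model_id} produced non-finite predictions")
    return np.clip(values, BG_MIN, BG_MAX)


# ----------------------------------------------------------------------- I/O
# Long-format delimited text: patient_id, timestamp, channel, value — plus a
# JSON sidecar mapping patient_id -> index of the first test step.


def write_series_csv(series_list, csv_path, split_path) -> None:
    rows = []
    split = {}
    for s in series_list:
        for c in CHANNELS:
            vals = getattr(s, c)
            for t, v in zip(s.timestamps, vals):
                if not np.isnan(v):
                    rows.append((s.patient_id, t, c, v))
        test_idx = s.partition_index("test")
        split[s.patient_id] = int(test_idx[0]) if test_idx.size else len(s)
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "channel", "value"]).to_csv(
        csv_path, index=False
    )
    with open(split_path, "w") as fh:
        json.dump(split, fh, indent=1)


def read_series_csv(csv_path, split_path) -> list:
    df = pd.read_csv(csv_path)
    with open(split_path) as fh:
        split = json.load(fh)
    out = []
    for pid, g in df.groupby("patient_id", sort=True):
        t0, t1 = g["timestamp"].min(), g["timestamp"].max()
        ts = np.arange(t0, t1 + SAMPLE_MINUTES, SAMPLE_MINUTES, dtype=float)
        pos = {t: i for i, t in enumerate(ts)}
        chans = {c: np.full(len(ts), np.nan) for c in CHANNELS}
        for _, row in g.iterrows():
            chans[row["channel"]][pos[row["timestamp"]]] = row["value"]
        for c in ("bas", "bol", "ch"):
            chans[c] = np.nan_to_num(chans[c])
        labels = np.array(
            ["train" if i < split[str(pid)] else "test" for i in range(len(ts))],
            dtype=object,
        )
        out.append(
            PatientSeries(
                patient_id=str(pid),
                timestamps=ts,
                split=labels,
                **chans,
            )
        )
    return out
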