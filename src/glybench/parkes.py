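"""Parkes (consensus) error grid for type-1 diabetes.

The grid partitions the (reference, prediction) square (0, 550]^2 mg/dL
into clinical-risk zones A-E: A means clinically accurate, B benign
deviation, and C-E increasingly dangerous treatment errors. Zone
boundaries are encoded from the published consensus vertex coordinates
for type 1 diabetes (Parkes et al., Diabetes Care 23:1143-1148, 2000, as
digitized to exact coordinates by Pfutzner et al., J Diabetes Sci
Technol 7:1275-1281, 2013). Below the diagonal the grid has no E zone.

Zones are tested inner-first (A, then B, C, D) with boundary-inclusive
polygon cover, so points exactly on a boundary are assigned to the
better zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .zoo import PredictionSet

__all__ = ["ZONES", "PEGResult", "peg_zone", "peg_zones", "peg_summary", "plot_peg"]

ZONES = ("A", "B", "C", "D", "E")
_LIMIT = 550.0

# Published type-1 consensus boundary polylines, (reference, prediction).
BOUNDARIES = {
    "b_upper": [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550)],
    "b_lower": [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)],
    "c_upper": [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550)],
    "c_lower": [(120, 0), (120, 30), (260, 130), (550, 250)],
    "d_upper": [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550)],
    "d_lower": [(250, 0), (250, 40), (550, 150)],
    "e_upper": [(0, 150), (35, 155), (50, 550)],
}


def _between(lower, upper) -> Polygon:
    """Closed polygon between a lower and an upper boundary polyline."""
    pts = [(0.0, 0.0)] + lower + [(_LIMIT, _LIMIT)] + upper[::-1]
    return Polygon(pts)


# nested regions: everything within the B lines is A, within the C lines
# is A-or-B, and so on; the innermost match wins.
_NESTED = [
    ("A", _between(BOUNDARIES["b_lower"], BOUNDARIES["b_upper"])),
    ("B", _between(BOUNDARIES["c_lower"], BOUNDARIES["c_upper"])),
    ("C", _between(BOUNDARIES["d_lower"], BOUNDARIES["d_upper"])),
    # type 1 has no lower E boundary: everything below the upper E line
    ("D", Polygon([(0, 0), (_LIMIT, 0), (_LIMIT, _LIMIT), (50, _LIMIT), (35, 155), (0, 150)])),
]


@dataclass
class PEGResult:
    """Zone tallies for one prediction set."""

    model_id: str
    horizon: int
    counts: dict  # zone -> int
    n: int

    @property
    def percentages(self) -> dict:
        return {z: 100.0 * c / self.n for z, c in self.counts.items()}

    @property
    def ab_percent(self) -> float:
        return 100.0 * (self.counts["A"] + self.counts["B"]) / self.n


def peg_zones(reference, prediction) -> np.ndarray:
    """Vectorized zone assignment for mg/dL arrays."""
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction must be aligned")
    bad = (ref <= 0) | (ref > _LIMIT) | (pred <= 0) | (pred > _LIMIT)
    if np.any(bad):
        raise ValueError("coordinates outside the (0, 550] mg/dL grid domain")
    pts = shapely.points(ref.ravel(), pred.ravel())
    out = np.full(pts.shape, "E", dtype=object)
    unassigned = np.ones(pts.shape, dtype=bool)
    for zone, poly in _NESTED:
        hit = unassigned & shapely.covers(poly, pts)
        out[hit] = zone
        unassigned &= ~hit
    return out.reshape(ref.shape)


def peg_zone(reference: float, prediction: float) -> str:
    """Zone of a single (reference, prediction) pair."""
    return str(peg_zones(np.array([reference]), np.array([prediction]))[0])


def peg_summary(preds: PredictionSet) -> PEGResult:
    """Tally zones for a prediction set (reference = actual glucose)."""
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    zones = peg_zones(preds.actual, preds.predicted)
    counts = {z: int(np.sum(zones == z)) for z in ZONES}
    return PEGResult(preds.model_id, preds.horizon, counts, len(preds))


def plot_peg(preds: PredictionSet, ax=None):
    """Scatter of predictions vs. reference with zone boundary overlays."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, line in BOUNDARIES.items():
        xs, ys = zip(*line)
        ax.plot(xs, ys, lw=0.8, color="grey")
    ax.plot([0, _LIMIT], [0, _LIMIT], lw=0.8, color="black")
    ax.scatter(preds.actual, preds.predicted, s=4, alpha=0.4)
    ax.set_xlim(0, _LIMIT)
    ax.set_ylim(0, _LIMIT)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.set_title(f"{preds.model_id}, {preds.horizon} min")
    return ax
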