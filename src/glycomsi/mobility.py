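"""Drift-time classification of glucose polymers versus N-glycans.

In the multiplexed assay (PNGase F + isoamylase on the same section),
released glucose polymers and N-glycans overlap in m/z but migrate
differently through the traveling-wave ion mobility cell.  For singly
charged ions of one chemical class, drift time grows approximately as the
square root of m/z, so each class traces a line in the drift vs sqrt(m/z)
plane.  We fit one line per class from ions confidently identified by mass
alone (ladder matches), then assign every ion to the class with the
smaller scaled residual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POLYMER",
    "GLYCAN",
    "UNASSIGNED",
    "MobilityPoint",
    "MobilityModel",
    "fit_mobility_model",
    "classify_ions",
    "points_table",
]

POLYMER = "glucose_polymer"
GLYCAN = "n_glycan"
UNASSIGNED = "unassigned"
_CLASSES = (POLYMER, GLYCAN)


@dataclass(frozen=True)
class MobilityPoint:
    """One ion in the drift-time x m/z plane."""

    mz: float
    drift: float  # ms
    intensity: float = 1.0
    assigned_class: str = UNASSIGNED
    residual: float = float("nan")  # ms, from the assigned class trend

    def __post_init__(self) -> None:
        if self.drift <= 0:
            raise ValueError(f"drift must be positive, got {self.drift}")


@dataclass(frozen=True)
class ClassTrend:
    slope: float      # ms per sqrt(Th)
    intercept: float  # ms
    residual_scale: float  # robust sigma, ms
    n_support: int

    def predict(self, mz: np.ndarray) -> np.ndarray:
        return self.slope * np.sqrt(mz) + self.intercept


@dataclass(frozen=True)
class MobilityModel:
    """Per-class linear trends drift = a*sqrt(m/z) + b with robust scales."""

    trends: dict[str, ClassTrend]


def fit_mobility_model(points: Iterable[MobilityPoint]) -> MobilityModel:
    """Least-squares fit of the per-class drift trends from labeled seeds.

    Requires >= 3 labeled points per class.  The residual scale is the
    median absolute residual scaled by 1.4826 (consistent with a Gaussian
    sigma), floored at a small positive value so noiseless fits still give
    a usable scale.
    """
    by_class: dict[str, list[MobilityPoint]] = {c: [] for c in _CLASSES}
    for p in points:
        if p.assigned_class in by_class:
            by_class[p.assigned_class].append(p)
    trends = {}
    for cls in _CLASSES:
        pts = by_class[cls]
        if len(pts) < 3:
            raise ValueError(
                f"class {cls!r} has {len(pts)} labeled points; >= 3 required"
            )
        x = np.sqrt([p.mz for p in pts])
        y = np.array([p.drift for p in pts])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        scale = 1.4826 * np.median(np.abs(resid))
        scale = max(float(scale), 1e-9)
        trends[cls] = ClassTrend(slope=float(slope), intercept=float(intercept),
                                 residual_scale=scale, n_support=len(pts))
    return MobilityModel(trends=trends)


def classify_ions(points: Sequence[MobilityPoint], model: MobilityModel,
                  max_sigma: float = 4.0) -> list[MobilityPoint]:
    """Assign each ion to the class with the smaller scaled drift residual.

    A point whose best scaled residual exceeds ``max_sigma`` stays
    unassigned.  Exact ties go to the glucose-polymer class.  Deterministic
    and independent of input order.
    """
    if max_sigma <= 0:
        raise ValueError(f"max_sigma must be positive, got {max_sigma}")
    out = []
    for p in points:
        scored = []
        for cls in _CLASSES:  # polymer first: wins exact ties
            trend = model.trends[cls]
            resid = p.drift - float(trend.predict(np.array([p.mz]))[0])
            scored.append((abs(resid) / trend.residual_scale, cls, resid))
        best = min(scored, key=lambda t: t[0])
        if best[0] <= max_sigma:
            out.append(replace(p, assigned_class=best[1], residual=best[2]))
        else:
            out.append(replace(p, assigned_class=UNASSIGNED,
                               residual=float("nan")))
    return out


def points_table(points: Sequence[MobilityPoint]) -> pd.DataFrame:
    """Labeled point export (mz, drift, intensity, class, residual)."""
    return pd.DataFrame(
        [{"mz": p.mz, "drift": p.drift, "intensity": p.intensity,
          "class": p.assigned_class, "residual": p.residual} for p in points]
    )
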