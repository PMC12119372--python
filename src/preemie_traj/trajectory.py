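"""Postnatal trajectory classification.

Each protein's per-day median profile (over infant samples, imputed data)
is scored against theoretical shapes with a squared Pearson correlation
(similarity score) and summarized by a signed baseline-normalized area
(effect size, trapezoid rule on the postnatal-day axis).  Proteins with
similarity >= r2_min and |area| >= area_min are classified as increasing
or decreasing according to the sign of the area; everything else is
stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import QuantTable, SampleSheet

__all__ = [
    "ShapeTemplate",
    "TrajectoryConfig",
    "linear_shape",
    "saturating_shape",
    "make_shapes",
    "median_profile",
    "similarity_score",
    "effect_area",
    "classify_trajectory",
    "summarize_trajectories",
]

INCREASING = "increasing"
DECREASING = "decreasing"
STABLE = "stable"


@dataclass
class ShapeTemplate:
    """A theoretical trajectory, one value per timepoint day."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2 or np.var(self.values) == 0:
            raise ValueError(f"shape {self.name!r} must be non-constant")


def linear_shape(days) -> ShapeTemplate:
    """Linear ramp in postnatal day (the default theoretical shape)."""
    return ShapeTemplate("linear_day", np.asarray(days, dtype=float))


def saturating_shape(days, rate: float = 3.0) -> ShapeTemplate:
    """Saturating-exponential ramp, plateauing at the last day."""
    d = np.asarray(days, dtype=float)
    span = d[-1] - d[0]
    return ShapeTemplate("saturating", 1.0 - np.exp(-rate * (d - d[0]) / span))


def make_shapes(names, days) -> list[ShapeTemplate]:
    shapes = []
    for name in names:
        if name in ("linear", "linear_day"):
            shapes.append(linear_shape(days))
        elif name == "saturating":
            shapes.append(saturating_shape(days))
        else:
            raise ValueError(f"unknown shape template {name!r}")
    return shapes


@dataclass
class TrajectoryConfig:
    r2_min: float = 0.5
    area_min: float = 20.0
    x_axis: str = "day"  # or "index"
    shapes: tuple[str, ...] = ("linear",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.area_min < 0:
            raise ValueError("area_min must be >= 0")
        if self.x_axis not in ("day", "index"):
            raise ValueError("x_axis must be 'day' or 'index'")


def median_profile(table: QuantTable, sheet: SampleSheet) -> pd.DataFrame:
    """Per-protein, per-day median over all infant samples (imputed data).

    Returns a proteins x days frame with integer day columns.
    """
    days = sheet.days
    if not days:
        raise ValueError("sample sheet contains no infant samples")
    cols = {}
    for day in days:
        ids = [s for s in sheet.ids("infant", day=day) if s in table.lfq.columns]
        if not ids:
            raise ValueError(f"no infant samples at day {day}")
        cols[day] = table.lfq[ids].median(axis=1)
    profile = pd.DataFrame(cols)
    profile.index.name = "protein"
    return profile


def similarity_score(values, shape: ShapeTemplate) -> float:
    """Squared Pearson correlation between a median profile and a shape.

    Zero-variance profiles return 0 by convention so constant proteins are
    always classified stable.
    """
    y = np.asarray(values, dtype=float)
    x = shape.values
    if y.shape != x.shape:
        raise ValueError(f"profile length {y.size} != shape length {x.size}")
    if np.var(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def effect_area(values, days, x_axis: str = "day") -> float:
    """Signed trapezoid area of the baseline-normalized profile.

    The first timepoint's median is subtracted from every median (so the
    curve starts at zero) and the deltas are integrated over the postnatal
    day (default) or the timepoint index.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("effect area needs at least 2 timepoints")
    x = np.asarray(days, dtype=float) if x_axis == "day" else np.arange(y.size, dtype=float)
    deltas = y - y[0]
    return float(np.trapezoid(deltas, x))


def classify_trajectory(similarity: float, area: float,
                        config: TrajectoryConfig) -> str:
    if similarity >= config.r2_min and area >= config.area_min:
        return INCREASING
    if similarity >= config.r2_min and area <= -config.area_min:
        return DECREASING
    return STABLE


def summarize_trajectories(table: QuantTable, sheet: SampleSheet,
                           config: TrajectoryConfig) -> pd.DataFrame:
    """Score and classify every protein; machine-readable trajectory table.

    When several shape templates are configured the per-protein similarity
    is the maximum over shapes and ``best_shape`` records the argmax.
    """
    profile = median_profile(table, sheet)
    days = list(profile.columns)
    shapes = make_shapes(config.shapes, days)
    rows = []
    for protein, values in profile.iterrows():
        v = values.to_numpy(float)
        scores = [(similarity_score(v, shape), shape.name) for shape in shapes]
        r2, best = max(scores, key=lambda t: t[0])
        area = effect_area(v, days, config.x_axis)
        rows.append((protein, r2, area, best, classify_trajectory(r2, area, config)))
    out = pd.DataFrame(rows, columns=["protein", "similarity", "effect_area",
                                      "best_shape", "trajectory_class"])
    out = out.set_index("protein")
    out.insert(0, "gene", table.genes.reindex(out.index))
    for day in days:
        out[f"median_day_{day}"] = profile[day]
    return out
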