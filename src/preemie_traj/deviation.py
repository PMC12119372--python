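"""SGA-vs-AGA longitudinal deviation screen.

For each protein and each group the per-day median profile is reduced to a
longitudinal CV (100*SD/mean across days, linear scale by default); the
trend difference is delta_cv = cv_SGA - cv_AGA.  The level difference is
the log2 fold change between the group medians pooled over all timepoints.
Proteins are categorized by the 2x2 of |delta_cv| > cv_stable_max and
group_lfc falling outside the empirical quantile window of the
all-protein LFC distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import QuantTable, SampleSheet
from .trajectory import median_profile

__all__ = [
    "DeviationConfig",
    "group_median_profile",
    "longitudinal_cv",
    "group_lfc",
    "flag_deviation",
    "summarize_deviation",
    "CONCORDANT",
    "DIFFERENT_TREND",
    "DIFFERENT_LEVEL",
    "DIFFERENT_BOTH",
]

CONCORDANT = "concordant"
DIFFERENT_TREND = "different_trend"
DIFFERENT_LEVEL = "different_level_similar_trend"
DIFFERENT_BOTH = "different_both"


@dataclass
class DeviationConfig:
    cv_stable_max: float = 30.0
    quantile_low: float = 0.05
    quantile_high: float = 0.95
    cv_scale: str = "linear"  # or "log2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantile_low < self.quantile_high <= 1.0:
            raise ValueError("quantiles must satisfy 0 <= low < high <= 1")
        if self.cv_stable_max <= 0:
            raise ValueError("cv_stable_max must be > 0")
        if self.cv_scale not in ("linear", "log2"):
            raise ValueError("cv_scale must be 'linear' or 'log2'")


def group_median_profile(table: QuantTable, sheet: SampleSheet,
                         group: str) -> pd.DataFrame:
    """Per-group, per-day medians over that group's infant samples."""
    ids = sheet.ids("infant", group=group)
    if not ids:
        raise ValueError(f"no infant samples for group {group!r}")
    sub = sheet.frame[sheet.frame["sample_id"].isin(ids)]
    missing_days = [d for d in sheet.days if not (sub["day"] == d).any()]
    if missing_days:
        raise ValueError(f"group {group!r} has no samples at days {missing_days}")
    group_sheet = SampleSheet(sub.copy())
    return median_profile(table.select_samples(
        [s for s in ids if s in table.lfq.columns]), group_sheet)


def longitudinal_cv(values, scale: str = "linear", input_log2: bool = True) -> float:
    """CV percent of the per-day median values across days.

    By default medians come in as log2 and the CV is computed on the
    back-transformed linear medians (sample SD, n-1).
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("longitudinal CV needs at least 2 days")
    if scale == "linear" and input_log2:
        y = np.power(2.0, y)
    mean = y.mean()
    if scale == "linear" and mean <= 0:
        raise ValueError("non-positive mean on linear scale")
    if mean == 0:
        raise ValueError("zero mean; CV undefined")
    return float(100.0 * y.std(ddof=1) / abs(mean))


def group_lfc(table: QuantTable, sheet: SampleSheet,
              group_a: str = "SGA", group_b: str = "AGA") -> pd.Series:
    """log2 fold change of pooled group medians (group_a - group_b).

    Medians are taken over all of a group's infant samples across all
    timepoints, on the log2 scale.
    """
    if table.scale != "log2":
        raise ValueError("group_lfc expects a log2-scale table")
    ids_a = [s for s in sheet.ids("infant", group=group_a) if s in table.lfq.columns]
    ids_b = [s for s in sheet.ids("infant", group=group_b) if s in table.lfq.columns]
    if not ids_a or not ids_b:
        raise ValueError("both groups must have at least one sample")
    lfc = table.lfq[ids_a].median(axis=1) - table.lfq[ids_b].median(axis=1)
    lfc.name = "group_lfc"
    return lfc


def flag_deviation(delta_cv: float, lfc: float, window: tuple[float, float],
                   config: DeviationConfig) -> str:
    """Assign the deviation category from the trend and level flags."""
    trend_dev = abs(delta_cv) > config.cv_stable_max
    q_low, q_high = window
    level_dev = (lfc < q_low) or (lfc > q_high)
    if trend_dev and level_dev:
        return DIFFERENT_BOTH
    if trend_dev:
        return DIFFERENT_TREND
    if level_dev:
        return DIFFERENT_LEVEL
    return CONCORDANT


def lfc_window(lfc_distribution, config: DeviationConfig) -> tuple[float, float]:
    """Empirical quantile window (linear interpolation) of the LFC ensemble."""
    dist = np.asarray(lfc_distribution, dtype=float)
    q_low = float(np.quantile(dist, config.quantile_low))
    q_high = float(np.quantile(dist, config.quantile_high))
    if q_low == q_high:
        warnings.warn("degenerate LFC distribution; no level deviations flagged")
    return q_low, q_high


def summarize_deviation(table: QuantTable, sheet: SampleSheet,
                        config: DeviationConfig,
                        group_a: str = "SGA",
                        group_b: str = "AGA") -> pd.DataFrame:
    """Full deviation screen: per-protein group CVs, delta CV, LFC, category."""
    prof_a = group_median_profile(table, sheet, group_a)
    prof_b = group_median_profile(table, sheet, group_b)
    input_log2 = table.scale == "log2"
    cv_a = prof_a.apply(
        lambda row: longitudinal_cv(row, config.cv_scale, input_log2), axis=1)
    cv_b = prof_b.apply(
        lambda row: longitudinal_cv(row, config.cv_scale, input_log2), axis=1)
    lfc = group_lfc(table, sheet, group_a, group_b)
    out = pd.DataFrame({
        "gene": table.genes.reindex(table.lfq.index),
        "cv_sga": cv_a,
        "cv_aga": cv_b,
        "delta_cv": cv_a - cv_b,
        "group_lfc": lfc,
    }, index=table.lfq.index)
    window = lfc_window(out["group_lfc"].to_numpy(), config)
    if window[0] == window[1]:
        out["category"] = [
            DIFFERENT_TREND if abs(d) > config.cv_stable_max else CONCORDANT
            for d in out["delta_cv"]
        ]
    else:
        out["category"] = [
            flag_deviation(d, l, window, config)
            for d, l in zip(out["delta_cv"], out["group_lfc"])
        ]
    out.index.name = "protein"
    out.attrs["lfc_window"] = window
    return out
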