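"""Downshifted-normal imputation of missing values and QC reproducibility screen."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .ingest import QuantTable

__all__ = ["ImputationParams", "impute_downshift", "qc_cv", "restrict_to_pass"]


@dataclass
class ImputationParams:
    """Parameters of the downshifted-normal imputation.

    Missing cells are drawn from Normal(mu - downshift*sigma,
    (width*sigma)^2) where mu and sigma are the mean and SD of the present
    log2 values of the scope unit (each sample column by default).
    """

    downshift: float = 1.8
    width: float = 0.3
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.scope not in ("per_sample", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")


def impute_downshift(table: QuantTable,
                     params: ImputationParams) -> tuple[QuantTable, pd.DataFrame]:
    """Fill missing log2 cells from a downshifted normal distribution.

    Returns the imputed table and a boolean mask marking imputed cells.
    Observed cells are never overwritten.  Deterministic given
    ``params.seed``.
    """
    if table.scale != "log2":
        raise ValueError("imputation expects a log2-scale table")
    values = table.lfq.to_numpy(float).copy()
    mask = np.isnan(values)
    if params.scope == "per_sample":
        for j, sample in enumerate(table.lfq.columns):
            col = values[:, j]
            present = col[~np.isnan(col)]
            if mask[:, j].any():
                if present.size < 2:
                    raise ValueError(
                        f"sample {sample!r} has fewer than 2 present values; "
                        "cannot estimate imputation distribution")
                mu, sd = present.mean(), present.std(ddof=1)
                n_missing = int(mask[:, j].sum())
                # per-sample substream keyed by sample id: draws do not
                # depend on column order, so re-reading a written report
                # reproduces the same imputation
                rng = stage_rng(params.seed, f"impute:{sample}")
                col[mask[:, j]] = rng.normal(mu - params.downshift * sd,
                                             params.width * sd, size=n_missing)
    else:
        rng = stage_rng(params.seed, "impute")
        present = values[~mask]
        if mask.any():
            if present.size < 2:
                raise ValueError("fewer than 2 present values in the table")
            mu, sd = present.mean(), present.std(ddof=1)
            values[mask] = rng.normal(mu - params.downshift * sd,
                                      params.width * sd, size=int(mask.sum()))
    lfq = pd.DataFrame(values, index=table.lfq.index, columns=table.lfq.columns)
    mask_frame = pd.DataFrame(mask, index=table.lfq.index, columns=table.lfq.columns)
    imputed = QuantTable(lfq=lfq, precursors=table.precursors.copy(),
                         genes=table.genes.copy(), scale="log2")
    return imputed, mask_frame


def qc_cv(table: QuantTable, threshold: float = 30.0) -> pd.DataFrame:
    """Coefficient of variation across repeated QC injections, per protein.

    ``table`` must be restricted to the QC injections.  CVs are computed on
    linear intensities (log2 tables are back-transformed) with the sample
    SD (n-1).  A protein passes iff ``cv_percent < threshold`` (strict) and
    fails with an undefined CV when any QC cell is missing.
    """
    if table.n_samples < 2:
        raise ValueError("QC CV needs at least 2 QC injections")
    values = table.lfq.to_numpy(float)
    if table.scale == "log2":
        values = np.power(2.0, values)
    complete = ~np.isnan(values).any(axis=1)
    # plain (non-nan) reductions: incomplete rows yield NaN without warnings
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * sd / mean
    result = pd.DataFrame({
        "mean": mean,
        "sd": sd,
        "cv_percent": cv,
        "pass": complete & (cv < threshold),
    }, index=table.lfq.index)
    result.index.name = "protein"
    result.attrs["threshold"] = threshold
    return result


def restrict_to_pass(table: QuantTable, qc_result: pd.DataFrame) -> QuantTable:
    """Keep only proteins whose QC CV passed the reproducibility screen."""
    passed = qc_result.index[qc_result["pass"].astype(bool)]
    passed = [p for p in table.lfq.index if p in set(passed)]
    if not passed:
        warnings.warn("no proteins passed the QC CV screen; returning empty table")
    return table.select_proteins(passed)
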