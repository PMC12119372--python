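"""Quantification-table ingest, precursor/completeness filtering, log2 transform.

The expected input dialects mimic a DIA-NN style protein-group report:

* ``wide_matrix`` — TSV with ``Protein.Group``, ``Genes`` followed by one
  intensity column per sample; unique-precursor counts live in a parallel
  TSV with the same layout.
* ``long_report`` — TSV with columns ``Protein.Group``, ``Genes``,
  ``Sample``, ``LFQ``, ``Unique.Precursors``.

Zero or empty intensities are treated as missing (standard LFQ convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "SampleSheet",
    "FilterConfig",
    "ReportFormatError",
    "read_report",
    "read_sample_sheet",
    "filter_min_precursors",
    "filter_completeness",
    "log2_transform",
]

COHORTS = ("infant", "adult", "qc")


class ReportFormatError(ValueError):
    """A quantification report or sample sheet violates the expected layout."""


@dataclass
class QuantTable:
    """Protein-group LFQ matrix with a parallel unique-precursor count matrix.

    Attributes
    ----------
    lfq:
        proteins x samples intensity matrix; ``NaN`` marks missing cells.
    precursors:
        proteins x samples integer matrix of unique-precursor counts;
        missing lfq cells carry a count of 0.
    genes:
        per-protein gene symbol(s), semicolon-joined for shared groups.
    scale:
        ``"linear"`` or ``"log2"``.
    """

    lfq: pd.DataFrame
    precursors: pd.DataFrame
    genes: pd.Series
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.lfq.index.is_unique:
            dups = self.lfq.index[self.lfq.index.duplicated()].unique().tolist()
            raise ReportFormatError(f"duplicated protein groups: {dups}")
        if self.precursors.shape != self.lfq.shape:
            raise ValueError("lfq and precursors shapes differ")
        if not (self.precursors.columns.equals(self.lfq.columns)
                and self.precursors.index.equals(self.lfq.index)):
            raise ValueError("lfq and precursors must share index and columns")
        self.genes = self.genes.reindex(self.lfq.index)
        # enforce count-0 convention on missing cells
        self.precursors = self.precursors.where(self.lfq.notna(), 0).astype(int)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.lfq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def n_proteins(self) -> int:
        return self.lfq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfq.shape[1]

    def select_proteins(self, proteins) -> "QuantTable":
        return QuantTable(
            lfq=self.lfq.loc[proteins].copy(),
            precursors=self.precursors.loc[proteins].copy(),
            genes=self.genes.loc[proteins].copy(),
            scale=self.scale,
        )

    def select_samples(self, samples) -> "QuantTable":
        samples = list(samples)
        return QuantTable(
            lfq=self.lfq[samples].copy(),
            precursors=self.precursors[samples].copy(),
            genes=self.genes.copy(),
            scale=self.scale,
        )

    def copy(self) -> "QuantTable":
        return QuantTable(self.lfq.copy(), self.precursors.copy(),
                          self.genes.copy(), self.scale)

    def to_wide_tsv(self, lfq_path, precursor_path=None) -> None:
        """Write the wide-matrix dialect (and optionally the count matrix)."""
        out = self.lfq.copy()
        out.insert(0, "Genes", self.genes)
        out.index.name = "Protein.Group"
        out.to_csv(lfq_path, sep="\t", na_rep="")
        if precursor_path is not None:
            cnt = self.precursors.copy()
            cnt.insert(0, "Genes", self.genes)
            cnt.index.name = "Protein.Group"
            cnt.to_csv(precursor_path, sep="\t")

    def to_long_tsv(self, path) -> None:
        """Write the long-report dialect (detected cells only)."""
        lfq = self.lfq.stack()
        cnt = self.precursors.stack().loc[lfq.index]
        frame = pd.DataFrame({
            "Protein.Group": lfq.index.get_level_values(0),
            "Genes": self.genes.loc[lfq.index.get_level_values(0)].to_numpy(),
            "Sample": lfq.index.get_level_values(1),
            "LFQ": lfq.to_numpy(),
            "Unique.Precursors": cnt.to_numpy().astype(int),
        })
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Per-sample metadata: subject, cohort, group and postnatal day."""

    frame: pd.DataFrame
    day_set: tuple[int, ...] | None = None

    REQUIRED = ("sample_id", "subject_id", "cohort", "group", "day")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ReportFormatError(f"sample sheet missing columns: {missing}")
        f = self.frame.copy()
        f["day"] = pd.to_numeric(f["day"], errors="coerce")
        if not f["sample_id"].is_unique:
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ReportFormatError(f"duplicated sample ids: {dups}")
        bad = set(f["cohort"]) - set(COHORTS)
        if bad:
            raise ReportFormatError(f"unknown cohorts: {sorted(bad)}")
        infants = f[f["cohort"] == "infant"]
        if infants["day"].isna().any():
            offenders = infants.loc[infants["day"].isna(), "sample_id"].tolist()
            raise ReportFormatError(f"infant samples without a day: {offenders}")
        if self.day_set is not None:
            off = infants[~infants["day"].isin(self.day_set)]
            if len(off):
                raise ReportFormatError(
                    f"infant days outside configured day set: {off['sample_id'].tolist()}")
        others = f[f["cohort"] != "infant"]
        if others["day"].notna().any():
            offenders = others.loc[others["day"].notna(), "sample_id"].tolist()
            raise ReportFormatError(f"non-infant samples carry a day: {offenders}")
        pairs = infants[["subject_id", "day"]]
        if pairs.duplicated().any():
            raise ReportFormatError("repeated (subject, day) pair among infant samples")
        self.frame = f.reset_index(drop=True)

    @property
    def days(self) -> list[int]:
        d = self.frame.loc[self.frame["cohort"] == "infant", "day"].dropna().unique()
        return sorted(int(x) for x in d)

    def ids(self, cohort: str, group: str | None = None,
            day: int | None = None) -> list[str]:
        f = self.frame[self.frame["cohort"] == cohort]
        if group is not None:
            f = f[f["group"] == group]
        if day is not None:
            f = f[f["day"] == day]
        return f["sample_id"].tolist()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["day"] = out["day"].astype("Int64")
        out.to_csv(path, index=False)


@dataclass
class FilterConfig:
    """Precursor and completeness filter thresholds (inclusive boundaries)."""

    min_unique_precursors: int = 2
    min_frac_per_timepoint: float = 0.50
    min_frac_per_group: float = 0.40

    def __post_init__(self) -> None:
        if self.min_unique_precursors < 1:
            raise ValueError("min_unique_precursors must be >= 1")
        for name in ("min_frac_per_timepoint", "min_frac_per_group"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def read_sample_sheet(path, day_set=None) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample sheet not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    return SampleSheet(frame, day_set=tuple(day_set) if day_set else None)


def _check_samples_known(samples, sheet: SampleSheet | None) -> None:
    if sheet is None:
        return
    known = set(sheet.frame["sample_id"])
    unknown = [s for s in samples if s not in known]
    if unknown:
        raise ReportFormatError(
            f"samples in report absent from sample sheet: {unknown}")


def read_report(path, dialect: str = "long_report",
                sheet: SampleSheet | None = None,
                precursor_path=None) -> QuantTable:
    """Read a quantification report into a linear-scale :class:`QuantTable`.

    Zero intensities are stored as missing.  When ``sheet`` is given, every
    sample column must appear in it.  For the wide dialect without a
    precursor matrix, present cells are assumed to have already passed the
    precursor filter and are assigned a count of ``2``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"report not found: {path}")
    if dialect == "wide_matrix":
        raw = pd.read_csv(path, sep="\t")
        for col in ("Protein.Group", "Genes"):
            if col not in raw.columns:
                raise ReportFormatError(f"wide report missing column {col!r}")
        if raw["Protein.Group"].duplicated().any():
            dups = raw.loc[raw["Protein.Group"].duplicated(), "Protein.Group"].tolist()
            raise ReportFormatError(f"duplicated protein groups: {dups}")
        raw = raw.set_index("Protein.Group")
        raw.index.name = None
        genes = raw.pop("Genes").astype(str)
        lfq = raw.astype(float)
        lfq = lfq.mask(lfq <= 0)
        if precursor_path is not None:
            praw = pd.read_csv(precursor_path, sep="\t")
            for col in ("Protein.Group", "Genes"):
                if col not in praw.columns:
                    raise ReportFormatError(f"precursor matrix missing column {col!r}")
            praw = praw.set_index("Protein.Group").drop(columns="Genes")
            cnt = praw.reindex(index=lfq.index, columns=lfq.columns).fillna(0).astype(int)
        else:
            cnt = pd.DataFrame(np.where(lfq.notna(), 2, 0),
                               index=lfq.index, columns=lfq.columns)
    elif dialect == "long_report":
        raw = pd.read_csv(path, sep="\t")
        needed = ("Protein.Group", "Genes", "Sample", "LFQ", "Unique.Precursors")
        for col in needed:
            if col not in raw.columns:
                raise ReportFormatError(f"long report missing column {col!r}")
        key = raw[["Protein.Group", "Sample"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ReportFormatError(
                f"duplicate rows for protein {dup['Protein.Group']!r} "
                f"sample {dup['Sample']!r}")
        lfq = raw.pivot(index="Protein.Group", columns="Sample", values="LFQ")
        lfq = lfq.mask(lfq <= 0)
        cnt = (raw.pivot(index="Protein.Group", columns="Sample",
                         values="Unique.Precursors")
               .reindex(index=lfq.index, columns=lfq.columns)
               .fillna(0).astype(int))
        genes = (raw.drop_duplicates("Protein.Group")
                 .set_index("Protein.Group")["Genes"]
                 .reindex(lfq.index).astype(str))
        lfq.columns.name = None
        cnt.columns.name = None
        lfq.index.name = None
        cnt.index.name = None
        genes.index.name = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_samples_known(lfq.columns, sheet)
    return QuantTable(lfq=lfq, precursors=cnt, genes=genes, scale="linear")


def filter_min_precursors(table: QuantTable, config: FilterConfig) -> QuantTable:
    """Blank every cell quantified from fewer than the required precursors.

    Cells are set to missing; no protein rows are dropped here.
    """
    keep = table.precursors >= config.min_unique_precursors
    lfq = table.lfq.where(keep)
    cnt = table.precursors.where(keep, 0)
    return QuantTable(lfq=lfq, precursors=cnt, genes=table.genes.copy(),
                      scale=table.scale)


def filter_completeness(table: QuantTable, sheet: SampleSheet,
                        config: FilterConfig) -> tuple[QuantTable, pd.DataFrame]:
    """Apply the per-timepoint / per-cohort identification-rate filter.

    A protein is retained for the infant cohort iff it is identified in at
    least ``min_frac_per_timepoint`` of the infant samples at *every*
    postnatal day and in at least ``min_frac_per_group`` of all infant
    samples.  It is retained for adults iff identified in at least
    ``min_frac_per_group`` of adult samples.  Proteins retained for neither
    cohort are removed.  QC samples are exempt.

    Returns the filtered table and a per-protein retention report with the
    per-timepoint fractions and the per-cohort decisions.
    """
    present = table.lfq.notna()
    report = pd.DataFrame(index=table.lfq.index)
    report.index.name = "protein"

    days = sheet.days
    infant_ok = pd.Series(True, index=table.lfq.index)
    infant_ids = sheet.ids("infant")
    for day in days:
        ids = sheet.ids("infant", day=day)
        ids = [s for s in ids if s in present.columns]
        if not ids:
            raise ValueError(f"no infant samples available at day {day}")
        frac = present[ids].mean(axis=1)
        report[f"frac_day_{day}"] = frac
        infant_ok &= frac >= config.min_frac_per_timepoint
    infant_ids = [s for s in infant_ids if s in present.columns]
    if infant_ids:
        frac_infant = present[infant_ids].mean(axis=1)
        report["frac_infant"] = frac_infant
        infant_ok &= frac_infant >= config.min_frac_per_group
    else:
        report["frac_infant"] = np.nan
        infant_ok &= False
    report["retained_infant"] = infant_ok

    adult_ids = [s for s in sheet.ids("adult") if s in present.columns]
    if adult_ids:
        frac_adult = present[adult_ids].mean(axis=1)
        report["frac_adult"] = frac_adult
        report["retained_adult"] = frac_adult >= config.min_frac_per_group
    else:
        report["frac_adult"] = np.nan
        report["retained_adult"] = False

    keep = report["retained_infant"] | report["retained_adult"]
    return table.select_proteins(table.lfq.index[keep]), report


def log2_transform(table: QuantTable) -> QuantTable:
    """Replace present intensities by their log2; missing cells stay missing."""
    if table.scale == "log2":
        raise ValueError("table is already log2 transformed")
    values = table.lfq.to_numpy(float)
    bad = values[~np.isnan(values)] <= 0
    if bad.any():
        raise ValueError("non-positive intensity encountered; cannot log2 transform")
    with np.errstate(invalid="ignore"):
        lfq = pd.DataFrame(np.log2(values), index=table.lfq.index,
                           columns=table.lfq.columns)
    return QuantTable(lfq=lfq, precursors=table.precursors.copy(),
                      genes=table.genes.copy(), scale="log2")
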