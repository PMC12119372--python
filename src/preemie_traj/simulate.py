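"""Synthetic longitudinal cohort generator.

Produces quantification tables and sample sheets with the statistical
structure the downstream analysis assumes — planted increasing /
decreasing / stable postnatal trajectories, an optional SGA-vs-AGA level
shift on a designated protein subset, whole-sample dropout following a
per-day availability pattern, intensity-dependent (MNAR) cell dropout,
unique-precursor counts, repeated QC-pool injections and an adult
reference cohort with an infant-only protein subset absent — together
with a ground-truth record so every stage can be tested without access
to clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stage_rng
from .ingest import QuantTable, SampleSheet

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "plant_profile",
    "simulate_intensities",
    "apply_missingness",
    "generate_cohort",
    "default_availability",
]

CLASSES = ("increasing", "decreasing", "stable")

# per-day availability fractions of the emulated design
# (31, 65, 56, 49, 27 samples out of 67 infants at days 0, 3, 7, 14, 28)
_AVAIL_FRACTIONS = (31 / 67, 65 / 67, 56 / 67, 49 / 67, 27 / 67)


def default_availability(n_infants: int, n_days: int = 5) -> tuple[int, ...]:
    """Scale the reference per-day availability pattern to a cohort size."""
    fr = _AVAIL_FRACTIONS
    if n_days != len(fr):
        fr = tuple(np.interp(np.linspace(0, 1, n_days),
                             np.linspace(0, 1, len(fr)), fr))
    return tuple(min(n_infants, max(1, round(f * n_infants))) for f in fr)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``mnar_slope == 0`` disables cell-level missingness entirely
    (detection probability 1); otherwise a cell of log2 intensity x is
    detected with probability logistic((x - mnar_midpoint) * mnar_slope).
    """

    n_proteins: int = 900
    n_aga: int = 49
    n_sga: int = 18
    n_adults: int = 6
    n_qc: int = 7
    days: tuple[int, ...] = (0, 3, 7, 14, 28)
    availability: tuple[int, ...] | None = None
    n_increasing: int = 150
    n_decreasing: int = 150
    n_stable: int = 600
    effect_magnitude_log2: float = 3.0
    group_shift_log2: float = 0.0
    n_group_shifted: int = 0
    noise_sd_log2: float = 0.3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.5
    mnar_midpoint: float = 14.0
    mnar_slope: float = 0.0
    min_precursor_lambda: float = 3.0
    qc_noise_sd_log2: float = 0.05
    n_adult_absent: int = 0
    profile_shape: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_proteins": self.n_proteins, "n_aga": self.n_aga,
                  "n_sga": self.n_sga, "n_adults": self.n_adults,
                  "n_qc": self.n_qc, "n_increasing": self.n_increasing,
                  "n_decreasing": self.n_decreasing, "n_stable": self.n_stable,
                  "n_group_shifted": self.n_group_shifted,
                  "n_adult_absent": self.n_adult_absent}
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_increasing + self.n_decreasing + self.n_stable != self.n_proteins:
            raise ValueError("class counts must sum to n_proteins")
        self.days = tuple(int(d) for d in self.days)
        if len(self.days) < 2 or any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing with length >= 2")
        n_infants = self.n_aga + self.n_sga
        if self.availability is None:
            self.availability = default_availability(n_infants, len(self.days))
        self.availability = tuple(int(a) for a in self.availability)
        if len(self.availability) != len(self.days):
            raise ValueError("availability must give one count per day")
        if any(a > n_infants for a in self.availability):
            raise ValueError("availability entries cannot exceed the cohort size")
        if any(a < 1 for a in self.availability):
            raise ValueError("availability entries must be >= 1")
        if self.effect_magnitude_log2 < 0:
            raise ValueError("effect_magnitude_log2 must be >= 0")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.min_precursor_lambda <= 0:
            raise ValueError("min_precursor_lambda must be > 0")
        if self.n_group_shifted > self.n_proteins:
            raise ValueError("n_group_shifted cannot exceed n_proteins")
        if self.n_adult_absent > self.n_proteins:
            raise ValueError("n_adult_absent cannot exceed n_proteins")
        if self.profile_shape not in ("linear", "saturating"):
            raise ValueError("profile_shape must be 'linear' or 'saturating'")

    @property
    def n_infants(self) -> int:
        return self.n_aga + self.n_sga


@dataclass
class GroundTruth:
    """What was planted: per-protein labels and the complete clean tensor."""

    protein_ids: list[str]
    classes: np.ndarray          # per protein, in CLASSES
    delta: np.ndarray            # planted plateau delta (log2) per protein
    group_shifted: np.ndarray    # bool per protein
    adult_absent: np.ndarray     # bool per protein
    subject_ids: list[str]
    subject_groups: np.ndarray   # "AGA"/"SGA" per subject
    days: tuple[int, ...]
    true_log2: np.ndarray        # protein x subject x day, pre-missingness

    def __post_init__(self) -> None:
        if not set(np.unique(self.classes)) <= set(CLASSES):
            raise ValueError("unknown trajectory class in ground truth")

    @property
    def class_series(self) -> pd.Series:
        return pd.Series(self.classes, index=self.protein_ids, name="planted_class")


def plant_profile(traj_class: str, baseline: float, delta: float,
                  days, shape: str = "linear") -> np.ndarray:
    """Expected log2 intensity per day for a planted trajectory.

    stable profiles are constant at the baseline; increasing/decreasing
    ones ramp to baseline +/- delta at the last day, either linearly in
    postnatal day (default) or along a saturating exponential.
    """
    d = np.asarray(days, dtype=float)
    if d.size == 0 or (d.size > 1 and np.any(np.diff(d) <= 0)):
        raise ValueError("days must be non-empty and strictly increasing")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if traj_class == "stable":
        return np.full(d.size, float(baseline))
    if traj_class not in ("increasing", "decreasing"):
        raise ValueError(f"unknown trajectory class {traj_class!r}")
    span = d[-1] - d[0]
    if shape == "linear":
        ramp = (d - d[0]) / span
    elif shape == "saturating":
        ramp = (1.0 - np.exp(-3.0 * (d - d[0]) / span)) / (1.0 - np.exp(-3.0))
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    sign = 1.0 if traj_class == "increasing" else -1.0
    return baseline + sign * delta * ramp


def simulate_intensities(config: GeneratorConfig) -> tuple[GroundTruth, np.ndarray]:
    """Draw the complete (pre-missingness) log2 intensity tensor.

    Baselines are log-normal on the linear scale, i.e. Normal on log2.
    Each subject's observation is the planted profile, plus the group
    shift for SGA subjects on group-shifted proteins, plus Gaussian
    residual noise.  Deterministic given ``config.seed``.
    """
    rng = stage_rng(config.seed, "simulate")
    n_p, n_s, n_d = config.n_proteins, config.n_infants, len(config.days)

    classes = np.array(["increasing"] * config.n_increasing
                       + ["decreasing"] * config.n_decreasing
                       + ["stable"] * config.n_stable)
    rng.shuffle(classes)
    delta = np.where(classes == "stable", 0.0, config.effect_magnitude_log2)

    group_shifted = np.zeros(n_p, dtype=bool)
    if config.n_group_shifted and config.group_shift_log2 != 0.0:
        # prefer stable proteins so the shift does not entangle with trends
        stable_idx = np.flatnonzero(classes == "stable")
        pool = stable_idx if stable_idx.size >= config.n_group_shifted \
            else np.arange(n_p)
        chosen = rng.choice(pool, size=config.n_group_shifted, replace=False)
        group_shifted[chosen] = True

    adult_absent = np.zeros(n_p, dtype=bool)
    if config.n_adult_absent:
        adult_absent[rng.choice(n_p, size=config.n_adult_absent, replace=False)] = True

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                           size=n_p)
    profiles = np.stack([
        plant_profile(c, b, dl, config.days, config.profile_shape)
        for c, b, dl in zip(classes, baselines, delta)
    ])  # n_p x n_d

    subject_ids = ([f"AGA{i + 1:03d}" for i in range(config.n_aga)]
                   + [f"SGA{i + 1:03d}" for i in range(config.n_sga)])
    subject_groups = np.array(["AGA"] * config.n_aga + ["SGA"] * config.n_sga)

    tensor = np.broadcast_to(profiles[:, None, :], (n_p, n_s, n_d)).copy()
    if config.group_shift_log2 != 0.0 and group_shifted.any():
        sga = subject_groups == "SGA"
        tensor[np.ix_(group_shifted, sga)] += config.group_shift_log2
    if config.noise_sd_log2 > 0:
        tensor += rng.normal(0.0, config.noise_sd_log2, size=tensor.shape)

    truth = GroundTruth(
        protein_ids=[f"P{i + 1:05d}" for i in range(n_p)],
        classes=classes,
        delta=delta,
        group_shifted=group_shifted,
        adult_absent=adult_absent,
        subject_ids=subject_ids,
        subject_groups=subject_groups,
        days=config.days,
        true_log2=tensor,
    )
    return truth, tensor


def _detected(rng, log2_values: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    if config.mnar_slope == 0.0:
        return np.ones(log2_values.shape, dtype=bool)
    p = expit((log2_values - config.mnar_midpoint) * config.mnar_slope)
    return rng.random(log2_values.shape) < p


def apply_missingness(truth: GroundTruth, tensor: np.ndarray,
                      config: GeneratorConfig) -> tuple[QuantTable, SampleSheet]:
    """Turn the clean tensor into an observed cohort.

    1. Whole-sample dropout: per day, only the configured number of
       available subjects contributes a sample (drawn without replacement).
    2. Cell-level MNAR dropout via the logistic detection curve.
    3. Detected cells get unique-precursor counts ~ 1 + Poisson(lambda).
    4. QC injections replicate the per-protein cohort mean with small
       noise; adults come from a separate baseline set with the
       adult-absent protein subset missing.
    """
    rng = stage_rng(config.seed, "missingness")
    n_p = len(truth.protein_ids)
    days = config.days

    aga_idx = np.flatnonzero(truth.subject_groups == "AGA")
    sga_idx = np.flatnonzero(truth.subject_groups == "SGA")

    columns: dict[str, np.ndarray] = {}
    rows = []
    for di, day in enumerate(days):
        avail = config.availability[di]
        # stratified dropout keeps the AGA:SGA mix of the cohort at every
        # day, so group-level contrasts stay estimable at all timepoints
        n_sga_day = int(round(avail * len(sga_idx) / config.n_infants))
        n_sga_day = min(max(n_sga_day, 1 if len(sga_idx) else 0), len(sga_idx))
        n_aga_day = avail - n_sga_day
        chosen = np.sort(np.concatenate([
            rng.choice(aga_idx, size=n_aga_day, replace=False),
            rng.choice(sga_idx, size=n_sga_day, replace=False),
        ]))
        for si in chosen:
            subject = truth.subject_ids[si]
            sid = f"{subject}_d{day:02d}"
            columns[sid] = tensor[:, si, di]
            rows.append((sid, subject, "infant", truth.subject_groups[si], day))

    # QC pool: per-protein mean over all infant cells, replicated injections
    pool_mean = tensor.mean(axis=(1, 2))
    for q in range(config.n_qc):
        sid = f"QC{q + 1:02d}"
        columns[sid] = pool_mean + rng.normal(0.0, config.qc_noise_sd_log2, n_p)
        rows.append((sid, "QCPOOL", "qc", "NA", None))

    adult_base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_p)
    for a in range(config.n_adults):
        sid = f"ADULT{a + 1:02d}"
        vals = adult_base + rng.normal(0.0, config.noise_sd_log2, n_p)
        vals = np.where(truth.adult_absent, np.nan, vals)
        columns[sid] = vals
        rows.append((sid, f"AD{a + 1:02d}", "adult", "NA", None))

    log2 = pd.DataFrame(columns, index=truth.protein_ids)
    detected = _detected(rng, log2.to_numpy(float), config) & log2.notna().to_numpy()
    counts = np.where(detected,
                      1 + rng.poisson(config.min_precursor_lambda, size=log2.shape),
                      0)
    lfq = pd.DataFrame(np.where(detected, np.power(2.0, log2.to_numpy(float)), np.nan),
                       index=log2.index, columns=log2.columns)
    genes = pd.Series([f"G{i + 1:05d}" for i in range(n_p)],
                      index=truth.protein_ids, name="gene")
    table = QuantTable(
        lfq=lfq,
        precursors=pd.DataFrame(counts, index=log2.index, columns=log2.columns),
        genes=genes,
        scale="linear",
    )
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "cohort", "group", "day"]))
    return table, sheet


def generate_cohort(config: GeneratorConfig) -> tuple[QuantTable, SampleSheet, GroundTruth]:
    """Full generator: clean tensor plus observed table and sample sheet."""
    truth, tensor = simulate_intensities(config)
    table, sheet = apply_missingness(truth, tensor, config)
    return table, sheet, truth
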