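"""Structured pipeline configuration (YAML) and its validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deviation import DeviationConfig
from .impute import ImputationParams
from .ingest import FilterConfig
from .simulate import GeneratorConfig
from .trajectory import TrajectoryConfig

__all__ = ["PipelineConfig", "load_config"]

MODES = ("analyze", "simulate+analyze")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, under a single global seed."""

    mode: str = "simulate+analyze"
    seed: int = 0
    report_path: str | None = None
    report_dialect: str = "long_report"
    precursor_path: str | None = None
    sample_sheet_path: str | None = None
    outdir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    qc_threshold: float = 30.0
    restrict_to_qc_pass: bool = False
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    alpha: float = 0.05
    lfc_min: float = 1.0
    differential_day: int = 0
    deviation: DeviationConfig = field(default_factory=DeviationConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "analyze":
            for name in ("report_path", "sample_sheet_path"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"analyze mode requires {name}")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{name} does not exist: {value}")
        # the global seed governs every stage's substream
        self.imputation.seed = self.seed
        self.generator.seed = self.seed


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    ``overrides`` (e.g. from CLI flags) take precedence over file values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    paths = raw.pop("paths", {})
    kwargs = dict(
        mode=raw.get("mode", "simulate+analyze"),
        seed=int(raw.get("seed", 0)),
        report_path=paths.get("report"),
        precursor_path=paths.get("precursors"),
        report_dialect=raw.get("report_dialect", "long_report"),
        sample_sheet_path=paths.get("sample_sheet"),
        outdir=raw.get("outdir", paths.get("outdir", "results")),
        filter=FilterConfig(**raw.get("filter", {})),
        imputation=ImputationParams(**raw.get("imputation", {})),
        qc_threshold=float(raw.get("qc", {}).get("threshold", 30.0)),
        restrict_to_qc_pass=bool(raw.get("qc", {}).get("restrict", False)),
        trajectory=_trajectory_config(raw.get("trajectory", {})),
        alpha=float(raw.get("differential", {}).get("alpha", 0.05)),
        lfc_min=float(raw.get("differential", {}).get("lfc_min", 1.0)),
        differential_day=int(raw.get("differential", {}).get("day", 0)),
        deviation=DeviationConfig(**raw.get("deviation", {})),
        generator=GeneratorConfig(**raw.get("generator", {})),
    )
    if overrides and overrides.get("seed") is not None:
        kwargs["seed"] = int(overrides["seed"])
    if overrides and overrides.get("outdir") is not None:
        kwargs["outdir"] = overrides["outdir"]
    return PipelineConfig(**kwargs)


def _trajectory_config(raw: dict) -> TrajectoryConfig:
    raw = dict(raw)
    if "shapes" in raw:
        raw["shapes"] = tuple(raw["shapes"])
    return TrajectoryConfig(**raw)
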