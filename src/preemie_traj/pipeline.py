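"""End-to-end orchestration: ingest -> filters -> log2 -> QC -> imputation
-> trajectory classification -> day-0 differential -> deviation screen."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .deviation import summarize_deviation
from .differential import call_significant, moderated_ttest, presence_sets
from .impute import impute_downshift, qc_cv, restrict_to_pass
from .ingest import (QuantTable, SampleSheet, filter_completeness,
                     filter_min_precursors, log2_transform, read_report,
                     read_sample_sheet)
from .simulate import generate_cohort
from .trajectory import summarize_trajectories

__all__ = ["PipelineError", "ResultBundle", "run_pipeline", "write_outputs"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ResultBundle:
    qc_result: pd.DataFrame
    retention: pd.DataFrame
    trajectory_summary: pd.DataFrame
    differential_result: pd.DataFrame
    deviation_result: pd.DataFrame
    imputation_mask: pd.DataFrame
    imputed: QuantTable
    sheet: SampleSheet
    manifest: dict
    simulated_table: QuantTable | None = None
    ground_truth: object | None = None


def _stage(name):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False
    return _ctx()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute all stages in order; byte-deterministic for a fixed seed."""
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "parameters": _params_dict(config),
        "stages": {},
    }
    truth = None
    simulated = None

    with _stage("ingest"):
        if config.mode == "simulate+analyze":
            table, sheet, truth = generate_cohort(config.generator)
            simulated = table
        else:
            sheet = read_sample_sheet(config.sample_sheet_path)
            table = read_report(config.report_path, config.report_dialect,
                                sheet=sheet, precursor_path=config.precursor_path)
    manifest["stages"]["ingest"] = {"proteins": table.n_proteins,
                                    "samples": table.n_samples}

    with _stage("precursor_filter"):
        table = filter_min_precursors(table, config.filter)
    manifest["stages"]["precursor_filter"] = {
        "present_cells": int(table.lfq.notna().to_numpy().sum())}

    with _stage("qc_cv"):
        qc_ids = sheet.ids("qc")
        if len(qc_ids) >= 2:
            qc_result = qc_cv(table.select_samples(qc_ids), config.qc_threshold)
        else:
            qc_result = pd.DataFrame(
                columns=["mean", "sd", "cv_percent", "pass"])
            qc_result.index.name = "protein"
    manifest["stages"]["qc_cv"] = {
        "qc_injections": len(qc_ids),
        "pass": int(qc_result["pass"].sum()) if len(qc_result) else 0}

    with _stage("completeness_filter"):
        table, retention = filter_completeness(table, sheet, config.filter)
        if config.restrict_to_qc_pass and len(qc_result):
            table = restrict_to_pass(table, qc_result)
    manifest["stages"]["completeness_filter"] = {"proteins": table.n_proteins}

    with _stage("log2"):
        table = log2_transform(table)

    with _stage("impute"):
        imputed, mask = impute_downshift(table, config.imputation)
    manifest["stages"]["impute"] = {
        "imputed_cells": int(mask.to_numpy().sum())}

    infant_ids = [s for s in sheet.ids("infant") if s in imputed.lfq.columns]
    infant_table = imputed.select_samples(infant_ids)
    infant_proteins = retention.index[retention["retained_infant"].astype(bool)]
    infant_proteins = [p for p in infant_table.lfq.index if p in set(infant_proteins)]
    infant_table = infant_table.select_proteins(infant_proteins)

    with _stage("trajectory"):
        traj = summarize_trajectories(infant_table, sheet, config.trajectory)
    manifest["stages"]["trajectory"] = {
        cls: int((traj["trajectory_class"] == cls).sum())
        for cls in ("increasing", "decreasing", "stable")}

    with _stage("differential"):
        day = config.differential_day
        ids_sga = [s for s in sheet.ids("infant", group="SGA", day=day)
                   if s in infant_table.lfq.columns]
        ids_aga = [s for s in sheet.ids("infant", group="AGA", day=day)
                   if s in infant_table.lfq.columns]
        diff = moderated_ttest(infant_table.lfq[ids_sga], infant_table.lfq[ids_aga])
        diff = call_significant(diff, config.alpha, config.lfc_min)
        diff.insert(0, "gene", infant_table.genes.reindex(diff.index))
    manifest["stages"]["differential"] = {
        "day": day, "n_sga": len(ids_sga), "n_aga": len(ids_aga),
        "significant": int(diff["significant"].sum())}

    with _stage("deviation"):
        dev = summarize_deviation(infant_table, sheet, config.deviation)
    manifest["stages"]["deviation"] = {
        cat: int((dev["category"] == cat).sum())
        for cat in sorted(dev["category"].unique())}

    sets = presence_sets(retention)
    manifest["stages"]["presence"] = {k: len(v) for k, v in sets.items()}

    return ResultBundle(
        qc_result=qc_result,
        retention=retention,
        trajectory_summary=traj,
        differential_result=diff,
        deviation_result=dev,
        imputation_mask=mask,
        imputed=imputed,
        sheet=sheet,
        manifest=manifest,
        simulated_table=simulated,
        ground_truth=truth,
    )


def _params_dict(config: PipelineConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        if f.name == "outdir":
            # destination-independent manifests: identical analyses are
            # byte-identical wherever they are written
            continue
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = dataclasses.asdict(value)
        else:
            out[f.name] = value
    return out


def _tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", na_rep="", index=index)


def write_outputs(bundle: ResultBundle, outdir) -> list[Path]:
    """Write every result table as TSV plus a JSON run manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise PipelineError("write_outputs", exc) from exc

    written = []

    def emit(frame, name, index=True):
        path = outdir / name
        _tsv(frame, path, index=index)
        written.append(path)

    emit(bundle.qc_result, "qc_cv.tsv")
    emit(bundle.retention, "retention_report.tsv")
    emit(bundle.trajectory_summary, "trajectory_summary.tsv")
    emit(bundle.differential_result, "differential.tsv")
    emit(bundle.deviation_result, "deviation.tsv")
    emit(bundle.imputation_mask, "imputation_mask.tsv")

    imputed_path = outdir / "imputed_log2.tsv"
    bundle.imputed.to_wide_tsv(imputed_path)
    written.append(imputed_path)

    if bundle.simulated_table is not None:
        sim_path = outdir / "simulated_report.tsv"
        bundle.simulated_table.to_long_tsv(sim_path)
        written.append(sim_path)
        sheet_path = outdir / "sample_sheet.csv"
        bundle.sheet.to_csv(sheet_path)
        written.append(sheet_path)
    if bundle.ground_truth is not None:
        truth = bundle.ground_truth
        gt = pd.DataFrame({
            "planted_class": truth.classes,
            "planted_delta_log2": truth.delta,
            "group_shifted": truth.group_shifted,
            "adult_absent": truth.adult_absent,
        }, index=pd.Index(truth.protein_ids, name="protein"))
        emit(gt, "ground_truth.tsv")

    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(manifest_path)
    return written
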