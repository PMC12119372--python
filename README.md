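# preemie-traj

Longitudinal serum-proteomics analysis for preterm-infant cohorts:
label-free quantification (LFQ) filtering, missing-not-at-random
imputation, QC reproducibility screening, postnatal trajectory
classification, moderated differential abundance at birth, and
SGA-vs-AGA longitudinal deviation detection — plus a synthetic cohort
generator so the whole pipeline is testable without access to clinical
data.

## Pipeline stages

1. **Ingest** (`preemie_traj.ingest`) — read DIA-NN-style protein-group
   reports (wide matrix or long TSV) and a sample sheet
   (`sample_id,subject_id,cohort,group,day`).
2. **Precursor filter** — blank LFQ cells quantified from fewer than 2
   unique precursors.
3. **Completeness filter** — keep proteins identified in ≥ 50% of infant
   samples at every postnatal day and ≥ 40% of a cohort's samples
   (infants or adults); emits a per-protein retention report.
4. **QC screen** (`preemie_traj.impute.qc_cv`) — coefficient of variation
   across repeated QC-pool injections on linear intensities; pass =
   CV < 30% (strict).
5. **Imputation** — missing log2 cells drawn per sample from
   Normal(μ − 1.8·σ, (0.3·σ)²) of the observed distribution.
6. **Trajectory classification** (`preemie_traj.trajectory`) — per-day
   median profiles over infants, similarity score (squared Pearson
   correlation against theoretical shapes, linear-in-day ramp by
   default), signed baseline-normalized trapezoid area over postnatal
   days; increasing/decreasing calls at r² ≥ 0.5 and |area| ≥ 20.
7. **Differential abundance** (`preemie_traj.differential`) — re-implemented
   empirical-Bayes moderated t-test (moment estimation of the variance
   prior via digamma/trigamma matching), Benjamini–Hochberg adjustment,
   significance at p_adj < 0.05 and |LFC| > 1 (both strict), plus a
   qualitative infant/adult presence comparison.
8. **Deviation screen** (`preemie_traj.deviation`) — per-group
   longitudinal CV of the median profiles, ΔCV = CV(SGA) − CV(AGA),
   pooled-median LFC, and categorization against the 30% CV rule and the
   empirical 5%/95% LFC window.

The synthetic generator (`preemie_traj.simulate`) plants
increasing/decreasing/stable trajectories, group-level shifts,
logistic-in-intensity (MNAR) dropout, per-day sample availability,
unique-precursor counts, QC-pool injections and an adult cohort with an
infant-only protein subset, and returns the ground truth for testing.

## CLI

All commands take a YAML config (see `examples/config.yaml`), with
`--seed` and `--outdir` overrides. One global seed drives per-stage
substreams; a fixed seed gives byte-identical outputs.

```sh
preemie-traj simulate --config examples/config.yaml --outdir out   # write synthetic inputs
preemie-traj all      --config examples/config.yaml --outdir out   # simulate + analyze
preemie-traj run      --config examples/config.yaml --outdir out   # analyze existing data
```

Outputs: `qc_cv.tsv`, `retention_report.tsv`, `trajectory_summary.tsv`,
`differential.tsv`, `deviation.tsv`, `imputation_mask.tsv`,
`imputed_log2.tsv`, a JSON run manifest, and (in simulate mode) the
generated report, sample sheet and ground truth.

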