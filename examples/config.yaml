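# End-to-end simulate+analyze configuration emulating the cohort design:
# 67 preterm infants (49 AGA / 18 SGA), postnatal days 0/3/7/14/28 with
# per-day availability 31/65/56/49/27, 6 adults, 7 QC-pool injections.
mode: simulate+analyze
seed: 1
outdir: results/example

filter:
  min_unique_precursors: 2
  min_frac_per_timepoint: 0.50
  min_frac_per_group: 0.40

imputation:
  downshift: 1.8
  width: 0.3
  scope: per_sample

qc:
  threshold: 30.0
  restrict: false

trajectory:
  r2_min: 0.5
  area_min: 20.0
  x_axis: day
  shapes: [linear]

differential:
  alpha: 0.05
  lfc_min: 1.0
  day: 0

deviation:
  cv_stable_max: 30.0
  quantile_low: 0.05
  quantile_high: 0.95

generator:
  n_proteins: 900
  n_increasing: 150
  n_decreasing: 150
  n_stable: 600
  n_aga: 49
  n_sga: 18
  n_adults: 6
  n_qc: 7
  days: [0, 3, 7, 14, 28]
  availability: [31, 65, 56, 49, 27]
  effect_magnitude_log2: 3.0
  group_shift_log2: 1.5
  n_group_shifted: 30
  noise_sd_log2: 0.3
  mnar_midpoint: 14.0
  mnar_slope: 1.0
  min_precursor_lambda: 3.0
  n_adult_absent: 40

# analyze mode instead reads existing inputs:
# mode: analyze
# paths:
#   report: results/example/simulated_report.tsv
#   sample_sheet: results/example/sample_sheet.csv
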