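import numpy as np
import pytest

from preemie_traj.simulate import (GeneratorConfig, apply_missingness,
                                   default_availability, generate_cohort,
                                   plant_profile, simulate_intensities)


def small_config(**overrides):
    base = dict(n_proteins=40, n_increasing=10, n_decreasing=10, n_stable=20,
                n_aga=8, n_sga=4, n_adults=3, n_qc=3,
                availability=(6, 12, 10, 9, 5), noise_sd_log2=0.3,
                mnar_slope=0.0, seed=11)
    base.update(overrides)
    return GeneratorConfig(**base)


# ----------------------------------------------------------- plant_profile

def test_plant_profile_stable_constant():
    out = plant_profile("stable", 20.0, 4.0, [0, 3, 7, 14, 28])
    np.testing.assert_array_equal(out, np.full(5, 20.0))


def test_plant_profile_increasing_linear():
    # hand evaluation of 20 + 4*day/28
    out = plant_profile("increasing", 20.0, 4.0, [0, 3, 7, 14, 28])
    np.testing.assert_allclose(out, [20.0, 20.428571, 21.0, 22.0, 24.0],
                               atol=1e-3)


def test_plant_profile_decreasing_two_days():
    np.testing.assert_allclose(plant_profile("decreasing", 20.0, 4.0, [0, 28]),
                               [20.0, 16.0])


def test_plant_profile_saturating_hits_plateau():
    out = plant_profile("increasing", 10.0, 2.0, [0, 3, 7, 14, 28],
                        shape="saturating")
    assert out[0] == 10.0
    assert out[-1] == pytest.approx(12.0)
    assert np.all(np.diff(out) > 0)


def test_plant_profile_rejects_unknown_class():
    with pytest.raises(ValueError, match="unknown trajectory class"):
        plant_profile("spiky", 20.0, 1.0, [0, 3])


# ---------------------------------------------------------- configuration

def test_config_invariants():
    with pytest.raises(ValueError, match="sum to n_proteins"):
        small_config(n_stable=19)
    with pytest.raises(ValueError, match="strictly increasing"):
        small_config(days=(0, 3, 3, 14, 28))
    with pytest.raises(ValueError, match="exceed the cohort"):
        small_config(availability=(6, 13, 10, 9, 5))


def test_default_availability_matches_reference_design():
    assert default_availability(67) == (31, 65, 56, 49, 27)


# ------------------------------------------------------------- intensities

def test_simulate_seeded_determinism():
    cfg = small_config()
    _, t1 = simulate_intensities(cfg)
    _, t2 = simulate_intensities(cfg)
    np.testing.assert_array_equal(t1, t2)


def test_simulate_noiseless_equals_planted_profile():
    cfg = small_config(noise_sd_log2=0.0)
    truth, tensor = simulate_intensities(cfg)
    for p in range(cfg.n_proteins):
        expected = plant_profile(truth.classes[p], tensor[p, 0, 0],
                                 truth.delta[p], cfg.days)
        for s in range(cfg.n_infants):
            np.testing.assert_allclose(tensor[p, s], expected)


def test_simulate_residual_sd_law_of_large_numbers():
    cfg = small_config(n_proteins=200, n_increasing=0, n_decreasing=0,
                      n_stable=200, noise_sd_log2=0.5, seed=5)
    truth, tensor = simulate_intensities(cfg)
    # stable proteins: the planted profile is the per-protein constant baseline
    clean = np.array([plant_profile(c, b, d, cfg.days)
                      for c, b, d in zip(truth.classes,
                                         tensor.mean(axis=(1, 2)), truth.delta)])
    resid = tensor - clean[:, None, :]
    assert resid.size >= 10_000
    assert abs(resid.std() - 0.5) < 0.02


def test_group_shift_flags_and_values():
    cfg = small_config(noise_sd_log2=0.0, group_shift_log2=1.5,
                       n_group_shifted=5)
    truth, tensor = simulate_intensities(cfg)
    assert truth.group_shifted.sum() == 5
    sga = truth.subject_groups == "SGA"
    for p in np.flatnonzero(truth.group_shifted):
        diff = tensor[p, sga, 0].mean() - tensor[p, ~sga, 0].mean()
        assert diff == pytest.approx(1.5)


def test_no_shift_flag_invariant():
    truth, _ = simulate_intensities(small_config(group_shift_log2=0.0,
                                                 n_group_shifted=5))
    assert not truth.group_shifted.any()


# ------------------------------------------------------------- missingness

def test_no_cell_missingness_when_slope_zero():
    cfg = small_config(mnar_slope=0.0, n_adult_absent=0)
    table, sheet, _ = generate_cohort(cfg)
    assert not table.lfq.isna().any().any()


def test_availability_counts_in_sheet():
    cfg = GeneratorConfig(n_proteins=10, n_increasing=0, n_decreasing=0,
                          n_stable=10, n_aga=49, n_sga=18,
                          availability=(31, 65, 56, 49, 27), seed=2)
    _, sheet, _ = generate_cohort(cfg)
    counts = [len(sheet.ids("infant", day=d)) for d in (0, 3, 7, 14, 28)]
    assert counts == [31, 65, 56, 49, 27]


def test_mnar_midpoint_detection_rate():
    # 1e5 cells planted exactly at the MNAR midpoint -> ~50% detected
    cfg = GeneratorConfig(n_proteins=1000, n_increasing=0, n_decreasing=0,
                          n_stable=1000, n_aga=20, n_sga=5, n_adults=0, n_qc=0,
                          days=(0, 3, 7, 14), availability=(25, 25, 25, 25),
                          noise_sd_log2=0.0, baseline_log2_sd=0.0,
                          baseline_log2_mean=18.0, mnar_midpoint=18.0,
                          mnar_slope=2.0, seed=3)
    truth, tensor = simulate_intensities(cfg)
    table, sheet, = apply_missingness(truth, tensor, cfg)[:2]
    infant_cols = sheet.ids("infant")
    frac = table.lfq[infant_cols].notna().to_numpy().mean()
    assert table.lfq[infant_cols].size == 100_000
    assert abs(frac - 0.5) < 0.01


def test_mnar_monotone_in_intensity():
    cfg = GeneratorConfig(n_proteins=600, n_increasing=0, n_decreasing=0,
                          n_stable=600, n_aga=30, n_sga=10, n_adults=0, n_qc=0,
                          days=(0, 3), availability=(40, 40),
                          noise_sd_log2=0.0, baseline_log2_mean=18.0,
                          baseline_log2_sd=2.0, mnar_midpoint=18.0,
                          mnar_slope=1.0, seed=4)
    truth, tensor = simulate_intensities(cfg)
    table, sheet, = apply_missingness(truth, tensor, cfg)[:2]
    infant = table.lfq[sheet.ids("infant")]
    det_rate = infant.notna().mean(axis=1).to_numpy()
    planted = tensor[:, 0, 0]
    lo = det_rate[planted < np.quantile(planted, 0.25)].mean()
    hi = det_rate[planted > np.quantile(planted, 0.75)].mean()
    assert lo < hi


def test_precursor_counts_distribution():
    cfg = small_config(min_precursor_lambda=0.2)
    table, _, _ = generate_cohort(cfg)
    present = table.precursors.to_numpy()[table.lfq.notna().to_numpy()]
    assert present.min() >= 1
    # with lambda=0.2 a sizable fraction sits at exactly 1 (below the filter)
    assert 0.5 < (present == 1).mean() < 0.95


def test_adult_absent_proteins_missing_in_adults():
    cfg = small_config(n_adult_absent=6)
    table, sheet, truth = generate_cohort(cfg)
    adult_cols = sheet.ids("adult")
    absent = np.array(truth.protein_ids)[truth.adult_absent]
    assert table.lfq.loc[absent, adult_cols].isna().all().all()
    infant_cols = sheet.ids("infant")
    assert table.lfq.loc[absent, infant_cols].notna().all().all()


def test_generate_cohort_bit_reproducible():
    cfg = small_config(mnar_slope=1.0, mnar_midpoint=15.0)
    t1, s1, _ = generate_cohort(cfg)
    t2, s2, _ = generate_cohort(cfg)
    assert t1.lfq.equals(t2.lfq)
    assert t1.precursors.equals(t2.precursors)
    assert s1.frame.equals(s2.frame)
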