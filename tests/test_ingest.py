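import numpy as np
import pandas as pd
import pytest

from preemie_traj.ingest import (FilterConfig, QuantTable, ReportFormatError,
                                 SampleSheet, filter_completeness,
                                 filter_min_precursors, log2_transform,
                                 read_report, read_sample_sheet)

from conftest import make_sheet, make_table


# ---------------------------------------------------------------- reading

def _write_wide(tmp_path, frame, name="report.tsv"):
    path = tmp_path / name
    frame.to_csv(path, sep="\t", index=False)
    return path


def test_read_wide_roundtrip(tmp_path):
    frame = pd.DataFrame({
        "Protein.Group": ["P1", "P2", "P3"],
        "Genes": ["A", "B;C", "D"],
        "s1": [10.0, 20.0, 30.0],
        "s2": [11.0, 21.0, 31.0],
        "s3": [12.0, 22.0, 32.0],
        "s4": [13.0, 23.0, 33.0],
    })
    table = read_report(_write_wide(tmp_path, frame), "wide_matrix")
    assert table.lfq.shape == (3, 4)
    assert table.genes["P2"] == "B;C"
    assert table.scale == "linear"


def test_read_wide_zero_is_missing(tmp_path):
    frame = pd.DataFrame({
        "Protein.Group": ["P1"], "Genes": ["A"], "s1": [0.0], "s2": [5.0]})
    table = read_report(_write_wide(tmp_path, frame), "wide_matrix")
    assert np.isnan(table.lfq.loc["P1", "s1"])
    assert table.precursors.loc["P1", "s1"] == 0
    assert table.lfq.loc["P1", "s2"] == 5.0


def test_read_wide_missing_column(tmp_path):
    frame = pd.DataFrame({"Protein.Group": ["P1"], "s1": [1.0]})
    with pytest.raises(ReportFormatError, match="Genes"):
        read_report(_write_wide(tmp_path, frame), "wide_matrix")


def test_read_wide_duplicate_protein(tmp_path):
    frame = pd.DataFrame({
        "Protein.Group": ["P1", "P1"], "Genes": ["A", "A"], "s1": [1.0, 2.0]})
    with pytest.raises(ReportFormatError, match="duplicated"):
        read_report(_write_wide(tmp_path, frame), "wide_matrix")


def test_read_long_duplicate_cell(tmp_path):
    frame = pd.DataFrame({
        "Protein.Group": ["P1", "P1"], "Genes": ["A", "A"],
        "Sample": ["s1", "s1"], "LFQ": [1.0, 2.0],
        "Unique.Precursors": [2, 2]})
    path = tmp_path / "long.tsv"
    frame.to_csv(path, sep="\t", index=False)
    with pytest.raises(ReportFormatError, match="duplicate"):
        read_report(path, "long_report")


def test_read_report_unknown_sample_rejected(tmp_path):
    frame = pd.DataFrame({
        "Protein.Group": ["P1"], "Genes": ["A"], "sX": [1.0]})
    sheet = make_sheet([("s1", "S1", "infant", "AGA", 0)])
    with pytest.raises(ReportFormatError, match="sX"):
        read_report(_write_wide(tmp_path, frame), "wide_matrix", sheet=sheet)


def test_long_roundtrip(tmp_path):
    table = make_table({"s1": [4.0, np.nan], "s2": [8.0, 16.0]},
                       precursors={"s1": [3, 0], "s2": [2, 5]})
    path = tmp_path / "long.tsv"
    table.to_long_tsv(path)
    back = read_report(path, "long_report")
    pd.testing.assert_frame_equal(back.lfq, table.lfq)
    pd.testing.assert_frame_equal(back.precursors, table.precursors)


def test_sample_sheet_validation(tmp_path):
    sheet = make_sheet([("s1", "A", "infant", "AGA", 0),
                        ("s2", "A", "infant", "AGA", 3),
                        ("q1", "Q", "qc", "NA", None)])
    assert sheet.days == [0, 3]
    assert sheet.ids("infant", day=3) == ["s2"]
    with pytest.raises(ReportFormatError, match="subject, day"):
        make_sheet([("s1", "A", "infant", "AGA", 0),
                    ("s2", "A", "infant", "AGA", 0)])
    with pytest.raises(ReportFormatError, match="without a day"):
        make_sheet([("s1", "A", "infant", "AGA", None)])
    with pytest.raises(ReportFormatError, match="carry a day"):
        make_sheet([("s1", "A", "adult", "NA", 3)])
    path = tmp_path / "sheet.csv"
    sheet.to_csv(path)
    back = read_sample_sheet(path)
    assert back.ids("qc") == ["q1"]


# ------------------------------------------------------- precursor filter

def test_precursor_filter_boundary():
    table = make_table({"s1": [1e6, 1e6, 1e6]},
                       precursors={"s1": [1, 2, 3]})
    out = filter_min_precursors(table, FilterConfig())
    assert np.isnan(out.lfq.loc["P1", "s1"])      # 1 precursor -> blanked
    assert out.lfq.loc["P2", "s1"] == 1e6          # 2 precursors -> kept
    assert out.lfq.loc["P3", "s1"] == 1e6
    assert out.precursors.loc["P1", "s1"] == 0


def test_precursor_filter_noop_and_idempotent():
    table = make_table({"s1": [1.0, 2.0], "s2": [3.0, 4.0]},
                       precursors={"s1": [2, 5], "s2": [3, 2]})
    cfg = FilterConfig()
    once = filter_min_precursors(table, cfg)
    pd.testing.assert_frame_equal(once.lfq, table.lfq)
    twice = filter_min_precursors(once, cfg)
    pd.testing.assert_frame_equal(twice.lfq, once.lfq)


def test_precursor_filter_never_adds_cells():
    rng = np.random.default_rng(0)
    lfq = {f"s{j}": rng.uniform(1, 10, 20) for j in range(4)}
    cnt = {f"s{j}": rng.integers(0, 5, 20) for j in range(4)}
    table = make_table(lfq, precursors=cnt)
    out = filter_min_precursors(table, FilterConfig())
    assert out.lfq.notna().sum().sum() <= table.lfq.notna().sum().sum()


# ---------------------------------------------------- completeness filter

def _six_infant_sheet():
    rows = []
    for day in (0, 3):
        for i in range(6):
            rows.append((f"i{i}_d{day}", f"I{i}", "infant", "AGA", day))
    rows += [(f"a{i}", f"A{i}", "adult", "NA", None) for i in range(4)]
    return make_sheet(rows)


def test_completeness_boundary_inclusive():
    sheet = _six_infant_sheet()
    cols = {}
    # P1: present in exactly 3/6 at both days (50% per day, 50% overall)
    # P2: present 2/6 at day 0 (33%) and 6/6 at day 3
    # P3: never present in adults, full in infants
    for day in (0, 3):
        for i in range(6):
            p1 = 5.0 if i < 3 else np.nan
            p2 = 5.0 if (day == 3 or i < 2) else np.nan
            cols[f"i{i}_d{day}"] = [p1, p2, 5.0]
    for i in range(4):
        cols[f"a{i}"] = [5.0, 5.0, np.nan]
    table = make_table(cols)
    out, report = filter_completeness(table, sheet, FilterConfig())
    assert bool(report.loc["P1", "retained_infant"])          # 50% boundary
    assert not bool(report.loc["P2", "retained_infant"])      # 33% at day 0
    assert bool(report.loc["P2", "retained_adult"])           # kept via adults
    assert bool(report.loc["P3", "retained_infant"])
    assert not bool(report.loc["P3", "retained_adult"])
    assert set(out.lfq.index) == {"P1", "P2", "P3"}


def test_completeness_drops_protein_retained_nowhere():
    sheet = _six_infant_sheet()
    cols = {f"i{i}_d{day}": [np.nan] for day in (0, 3) for i in range(6)}
    cols.update({f"a{i}": [np.nan] for i in range(4)})
    cols["i0_d0"] = [5.0]
    table = make_table(cols)
    out, report = filter_completeness(table, sheet, FilterConfig())
    assert out.n_proteins == 0
    assert not report["retained_infant"].any()


def test_completeness_fractions_match_brute_force():
    rng = np.random.default_rng(7)
    sheet = _six_infant_sheet()
    samples = sheet.frame["sample_id"].tolist()
    lfq = {s: np.where(rng.random(30) < 0.6, 5.0, np.nan) for s in samples}
    table = make_table(lfq)
    _, report = filter_completeness(table, sheet, FilterConfig())
    present = table.lfq.notna()
    for day in (0, 3):
        ids = sheet.ids("infant", day=day)
        expected = present[ids].sum(axis=1) / len(ids)
        np.testing.assert_allclose(report[f"frac_day_{day}"], expected)


def test_completeness_idempotent():
    rng = np.random.default_rng(3)
    sheet = _six_infant_sheet()
    samples = sheet.frame["sample_id"].tolist()
    lfq = {s: np.where(rng.random(25) < 0.5, 4.0, np.nan) for s in samples}
    cfg = FilterConfig()
    once, _ = filter_completeness(make_table(lfq), sheet, cfg)
    twice, _ = filter_completeness(once, sheet, cfg)
    pd.testing.assert_frame_equal(once.lfq, twice.lfq)


# ------------------------------------------------------------------ log2

def test_log2_exact_values():
    table = make_table({"s1": [8.0, 1.0, np.nan]})
    out = log2_transform(table)
    assert out.lfq.loc["P1", "s1"] == 3.0
    assert out.lfq.loc["P2", "s1"] == 0.0
    assert np.isnan(out.lfq.loc["P3", "s1"])
    assert out.scale == "log2"


def test_log2_rejects_double_transform_and_nonpositive():
    table = make_table({"s1": [8.0]})
    out = log2_transform(table)
    with pytest.raises(ValueError, match="already log2"):
        log2_transform(out)
    with pytest.raises(ValueError, match="non-positive"):
        # bypass the reader's zero-as-missing conversion
        bad = make_table({"s1": [1.0]})
        bad.lfq.loc["P1", "s1"] = -2.0
        log2_transform(bad)
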