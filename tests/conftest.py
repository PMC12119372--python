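import numpy as np
import pandas as pd
import pytest

from preemie_traj.ingest import QuantTable, SampleSheet


def make_table(lfq: dict, precursors: dict | None = None,
               genes: dict | None = None, scale: str = "linear") -> QuantTable:
    """Build a QuantTable from {sample: [values...]} column dicts."""
    lfq_frame = pd.DataFrame(lfq, dtype=float)
    lfq_frame.index = [f"P{i + 1}" for i in range(len(lfq_frame))]
    if precursors is None:
        cnt = pd.DataFrame(np.where(lfq_frame.notna(), 2, 0),
                           index=lfq_frame.index, columns=lfq_frame.columns)
    else:
        cnt = pd.DataFrame(precursors, index=lfq_frame.index)
    gene_series = pd.Series(genes or {p: f"G_{p}" for p in lfq_frame.index},
                            index=lfq_frame.index)
    return QuantTable(lfq=lfq_frame, precursors=cnt, genes=gene_series, scale=scale)


def make_sheet(rows) -> SampleSheet:
    """rows: iterable of (sample_id, subject_id, cohort, group, day)."""
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "cohort", "group", "day"]))


@pytest.fixture
def tiny_sheet():
    rows = []
    for day in (0, 3, 7):
        for i in range(3):
            grp = "SGA" if i == 2 else "AGA"
            rows.append((f"S{i}_d{day}", f"S{i}", "infant", grp, day))
    rows += [("AD1", "AD1", "adult", "NA", None),
             ("AD2", "AD2", "adult", "NA", None),
             ("QC1", "QCPOOL", "qc", "NA", None),
             ("QC2", "QCPOOL", "qc", "NA", None)]
    return make_sheet(rows)
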