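import numpy as np
import pytest

from premap.peaklist_io import PeakRecord, PeakTable, SampleMeta


@pytest.fixture
def dia_meta():
    return SampleMeta(state="trp", magnetic="diamagnetic", protein_conc_uM=200.0,
                      construct="S220C-TEMPO")


@pytest.fixture
def para_meta():
    return SampleMeta(state="trp", magnetic="paramagnetic", covalent_label=True,
                      protein_conc_uM=200.0, construct="S220C-TEMPO")


def make_table(meta, rows):
    """rows: iterable of (residue_index, methyl_id, intensity, noise[, sh, sc])."""
    recs = []
    for row in rows:
        res, methyl, inten, noise = row[:4]
        sh, sc = (row[4], row[5]) if len(row) > 4 else (0.8, 21.0)
        recs.append(
            PeakRecord(residue_index=res, methyl_id=methyl, intensity=inten,
                       noise_sigma=noise, shift_H_ppm=sh, shift_C_ppm=sc)
        )
    return PeakTable.from_records(meta, recs)


@pytest.fixture
def simple_pair(dia_meta, para_meta):
    rows_dia = [(20, "V20-g1", 1000.0, 10.0), (197, "V197-g1", 1000.0, 10.0),
                (129, "I129-d1", 1000.0, 10.0)]
    rows_para = [(20, "V20-g1", 500.0, 10.0), (197, "V197-g1", 200.0, 10.0),
                 (129, "I129-d1", 800.0, 10.0)]
    return make_table(dia_meta, rows_dia), make_table(para_meta, rows_para)
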