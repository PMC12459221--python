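"""Shared input generation for the numbered analysis scripts.

All inputs are synthetic (no experimental spectra are deposited with the
study system); the generators plant known ground truth at the study
conditions so every downstream table can be checked against truth files.
Scripts call :func:`ensure_inputs` and get the same files regardless of
execution order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from premap.md_distances import write_snapshots_pdb
from premap.peaklist_io import write_peak_table
from premap.synthetic import (
    LoopEnsembleModel,
    SurfaceChargeModel,
    generate_pre_tables,
    generate_snapshots,
    generate_spre_tables,
)

SEED = 20260929
ROOT = Path(__file__).resolve().parent.parent
# regenerable inputs (incl. multi-frame PDBs) live under scratch/; only the
# small derived report tables go to results/
DATA = ROOT / "scratch" / "data"
TABLES = ROOT / "results" / "tables"

#: methyl probes in the frame of the spin label's home position (origin).
#: The proximal cluster sits 14–19 Å from home (well-resolved PREs without
#: bleaching); the distal group lies beyond the ~25 Å detection ceiling of
#: the home position and only lights up through loop excursions.
PROBES = {
    # proximal cluster: loop stubs and adjacent residues
    (211, "V211-g1"): np.array([14.0, 3.0, 0.0]),
    (214, "V214-g1"): np.array([13.0, -5.0, 2.0]),
    (225, "I225-d1"): np.array([15.0, 4.0, -3.0]),
    (128, "I128-d1"): np.array([16.0, 7.0, 3.0]),
    (129, "I129-d1"): np.array([13.0, 8.0, -2.0]),
    (230, "L230-d1"): np.array([14.0, 6.0, 5.0]),
    (231, "V231-g1"): np.array([15.0, 8.0, -4.0]),
    (233, "I233-d1"): np.array([17.0, 6.0, 6.0]),
    # distal group: active-site face (V20, V197) and outer tips
    (12, "L12-d1"): np.array([20.0, -26.0, 6.0]),
    (20, "V20-g1"): np.array([16.0, -24.0, 0.0]),
    (31, "I31-d1"): np.array([28.0, -20.0, -8.0]),
    (120, "V120-g1"): np.array([-32.0, 15.0, 10.0]),
    (197, "V197-g1"): np.array([15.0, -23.8, 1.6]),
    (237, "I237-d1"): np.array([-28.0, -22.0, 4.0]),
}

# Trp-bound form: the loop's label spends 8% of the time on an excursion
# toward the active-site face (near V20/V197), 92% at home.  Tyr-bound:
# the excursion population visits the opposite (upper) face instead.
EXCURSION_TRP = np.array([10.0, -16.0, 1.0])
EXCURSION_TYR = np.array([-20.0, -14.0, 5.0])
HOME = np.array([0.0, 0.0, 0.0])


def loop_model(state: str) -> LoopEnsembleModel:
    excursion = EXCURSION_TRP if state == "trp" else EXCURSION_TYR
    return LoopEnsembleModel(
        members=np.array([HOME, excursion]),
        weights=np.array([0.92, 0.08]),
        probe_sites=PROBES,
        noise_sigma=20.0,
    )


#: residues planted to gain positive surface charge in the mutant at low pH
CHARGE_GAIN_RESIDUES = (12, 19, 104, 185, 201, 211, 214, 237, 238, 251)


def charge_model(construct: str, pH: float) -> SurfaceChargeModel:
    """Planted surface charges: the mutant gains positive charge near the
    active site at low pH; the wild type is pH-stable.  Baseline |ψ| is kept
    ≥ 0.4 so every sample's ϕ stays resolvable against its uncertainty."""
    rng = np.random.default_rng(101)
    residues = sorted({res for res, _ in PROBES} | set(CHARGE_GAIN_RESIDUES))
    psi = {res: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.8))
           for res in residues}
    if construct == "D215A" and pH == 6.5:
        for res in CHARGE_GAIN_RESIDUES:
            psi[res] = psi.get(res, 0.0) + 1.2
    return SurfaceChargeModel(psi=psi, base_gamma2_per_s=20.0, noise_sigma=5.0)


def ensure_inputs(seed: int = SEED) -> Path:
    """Generate all synthetic inputs under results/data (idempotent)."""
    DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
    stamp = DATA / f".seed_{seed}"
    if stamp.exists():
        return DATA
    for state in ("trp", "tyr"):
        dia, para, truth = generate_pre_tables(loop_model(state), seed=seed, state=state)
        write_peak_table(dia, DATA / f"pre_{state}_dia.tsv")
        write_peak_table(para, DATA / f"pre_{state}_para.tsv")
        truth.to_csv(DATA / f"pre_{state}_truth.tsv", sep="\t", index=False)
    for construct in ("WT", "D215A"):
        for pH in (6.5, 7.5):
            tag = f"{construct.lower()}_{int(pH * 10)}"
            dia, plus, minus, truth = generate_spre_tables(
                charge_model(construct, pH), seed=seed + int(pH * 10),
                construct=construct, pH=pH)
            for name, table in (("dia", dia), ("plus", plus), ("minus", minus)):
                write_peak_table(table, DATA / f"spre_{tag}_{name}.tsv")
            truth.to_csv(DATA / f"spre_{tag}_truth.tsv", sep="\t", index=False)
    for state, f_close, offset in (("trp", 0.08, 11), ("tyr", 0.005, 13)):
        snaps, truth = generate_snapshots(n_frames=600, f_close_inter=f_close,
                                          seed=seed + offset)
        write_snapshots_pdb(snaps, DATA / f"snapshots_{state}.pdb")
        truth.to_csv(DATA / f"snapshots_{state}_truth.tsv", sep="\t", index=False)
    stamp.touch()
    return DATA
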