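"""Loop-to-active-site distance census over homodimer coordinate snapshots.

Given exported simulation snapshots of a two-chain homodimer, this module
measures the Euclidean distance between one reference atom in the flexible
loop (default: the S220 hydroxyl proton, heavy-atom fallback Oγ) and one in
the active site (default: the V197 Cγ1 methyl proton, fallback Cγ1), for all
four chain pairings per frame — A→A and B→B (intra-protomer), A→B and B→A
(inter-protomer) — and summarizes close-approach statistics against the
nitroxide-PRE observability thresholds: close approaches in [5, 15) Å,
intra-protomer floor at 25 Å.

Snapshots are read from multi-model PDB (via MDAnalysis) or from a plain
TSV of per-frame coordinates.  Coordinates are taken as-is: no periodic
minimum-image correction is applied unless box vectors are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnapshotSet",
    "AtomSelector",
    "DistanceCensus",
    "SnapshotValidationError",
    "SelectionError",
    "read_snapshots",
    "write_snapshots_pdb",
    "distance_series",
    "close_fraction",
    "min_class_distance",
    "distance_histogram",
    "CLOSE_LOW_A",
    "CLOSE_HIGH_A",
    "FAR_FLOOR_A",
]

CLOSE_LOW_A = 5.0
CLOSE_HIGH_A = 15.0
FAR_FLOOR_A = 25.0

_COORD_COLUMNS = ["frame", "chain", "residue_index", "atom_name", "x", "y", "z"]


class SnapshotValidationError(ValueError):
    """Snapshot input violating a structural precondition."""


class SelectionError(ValueError):
    """An atom selector resolving to zero or several atoms."""


@dataclass(frozen=True)
class AtomSelector:
    """One atom per chain per frame, with an optional heavy-atom fallback.

    ``chain=None`` is a template to be instantiated for each chain of the
    dimer.  If ``atom_name`` is absent from a frame (proton-free snapshot
    exports), ``fallback_atom_name`` is tried; a warning is issued once and
    the resolved name is recorded in census provenance.
    """

    residue_index: int
    atom_name: str
    chain: str | None = None
    fallback_atom_name: str | None = None


#: default selectors: loop apex hydroxyl proton and active-site methyl proton
LOOP_SELECTOR = AtomSelector(residue_index=220, atom_name="HG", fallback_atom_name="OG")
SITE_SELECTOR = AtomSelector(residue_index=197, atom_name="HG11", fallback_atom_name="CG1")


@dataclass
class SnapshotSet:
    """Ordered coordinate frames of a two-chain system.

    ``df`` columns: frame, chain, residue_index, atom_name, x, y, z (Å).
    ``frame_interval_ns`` is bookkeeping metadata only.
    """

    df: pd.DataFrame
    frame_interval_ns: float = 1.0
    rejected_frames: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in _COORD_COLUMNS if c not in self.df.columns]
        if missing:
            raise SnapshotValidationError(f"missing coordinate columns: {missing}")
        if not np.isfinite(self.df[["x", "y", "z"]].to_numpy()).all():
            raise SnapshotValidationError("non-finite coordinates")
        chains = sorted(self.df["chain"].unique())
        if len(chains) < 2:
            raise SnapshotValidationError(
                f"need two chains for inter-protomer analysis, found {chains}"
            )

    @property
    def chains(self) -> list[str]:
        return sorted(self.df["chain"].unique())

    @property
    def n_frames(self) -> int:
        return self.df["frame"].nunique()


def read_snapshots(path: str | Path, frame_interval_ns: float = 1.0) -> SnapshotSet:
    """Read snapshots from a multi-model PDB or a coordinate TSV.

    TSV input needs the columns frame, chain, residue_index, atom_name,
    x, y, z.  PDB models become frames 0..n−1 in model order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".csv", ".txt"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        df.columns = [c.lower() for c in df.columns]
        return SnapshotSet(df=df, frame_interval_ns=frame_interval_ns)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDA guesses elements on minimal PDBs
        u = mda.Universe(str(path))
        rows = []
        for i, _ in enumerate(u.trajectory):
            for atom in u.atoms:
                chain = atom.chainID if atom.chainID.strip() else atom.segid
                rows.append(
                    (i, chain, int(atom.resid), atom.name,
                     float(atom.position[0]), float(atom.position[1]),
                     float(atom.position[2]))
                )
    df = pd.DataFrame(rows, columns=_COORD_COLUMNS)
    return SnapshotSet(df=df, frame_interval_ns=frame_interval_ns)


def write_snapshots_pdb(snaps: SnapshotSet, path: str | Path) -> None:
    """Serialize a snapshot set as a multi-model PDB (via biotite)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    frames = sorted(snaps.df["frame"].unique())
    first = snaps.df[snaps.df["frame"] == frames[0]].sort_values(
        ["chain", "residue_index", "atom_name"]
    )
    n_atoms = len(first)
    coords = np.empty((len(frames), n_atoms, 3))
    for k, f in enumerate(frames):
        sub = snaps.df[snaps.df["frame"] == f].sort_values(
            ["chain", "residue_index", "atom_name"]
        )
        if len(sub) != n_atoms:
            raise SnapshotValidationError(f"frame {f}: inconsistent atom count")
        coords[k] = sub[["x", "y", "z"]].to_numpy()
    stack = struc.AtomArrayStack(len(frames), n_atoms)
    stack.coord = coords
    stack.chain_id = first["chain"].to_numpy(dtype="U4")
    stack.res_id = first["residue_index"].to_numpy(dtype=int)
    stack.atom_name = first["atom_name"].to_numpy(dtype="U6")
    resname = {220: "SER", 197: "VAL"}
    stack.res_name = np.array(
        [resname.get(i, "GLY") for i in first["residue_index"]], dtype="U4"
    )
    stack.element = np.array(
        [("H" if n.startswith("H") else n[0]) for n in first["atom_name"]], dtype="U2"
    )
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


@dataclass
class DistanceCensus:
    """Per-frame, per-chain-pair distances with classification.

    ``records`` columns: frame, chain_pair (e.g. "A->B"), klass
    ("inter"/"intra"), distance_A.  ``selector_provenance`` records which
    atom names actually resolved (proton or heavy-atom fallback).
    """

    records: pd.DataFrame
    close_low: float = CLOSE_LOW_A
    close_high: float = CLOSE_HIGH_A
    far_floor: float = FAR_FLOOR_A
    rejected_frames: list[tuple[int, str]] = field(default_factory=list)
    selector_provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for klass in ("inter", "intra"):
            sub = self.records[self.records["klass"] == klass]
            if len(sub) == 0:
                continue
            out[klass] = {
                "n": int(len(sub)),
                "fraction_close": close_fraction(self, klass, self.close_low, self.close_high),
                "min_A": float(sub["distance_A"].min()),
                "max_A": float(sub["distance_A"].max()),
            }
        return out


def _resolve(frame_df: pd.DataFrame, sel: AtomSelector, chain: str):
    """Return (xyz, resolved_atom_name) or raise/None."""
    for name in filter(None, (sel.atom_name, sel.fallback_atom_name)):
        hits = frame_df[
            (frame_df["chain"] == chain)
            & (frame_df["residue_index"] == sel.residue_index)
            & (frame_df["atom_name"] == name)
        ]
        if len(hits) > 1:
            raise SelectionError(
                f"selector ({chain}, {sel.residue_index}, {name}) matches "
                f"{len(hits)} atoms"
            )
        if len(hits) == 1:
            return hits[["x", "y", "z"]].to_numpy()[0], name
    return None, None


def distance_series(
    snaps: SnapshotSet,
    loop_sel: AtomSelector = LOOP_SELECTOR,
    site_sel: AtomSelector = SITE_SELECTOR,
    *,
    close_low: float = CLOSE_LOW_A,
    close_high: float = CLOSE_HIGH_A,
    far_floor: float = FAR_FLOOR_A,
) -> DistanceCensus:
    """Measure all four loop↔site chain pairings in every frame.

    Per frame: loop(A)→site(A) and loop(B)→site(B) are intra-protomer,
    loop(A)→site(B) and loop(B)→site(A) inter-protomer.  Frames where a
    selector cannot be resolved (even via fallback) are rejected and
    reported, not silently skipped.
    """
    chains = snaps.chains
    if len(chains) != 2:
        raise SnapshotValidationError(f"expected exactly 2 chains, found {chains}")
    provenance: dict = {}
    fallback_warned = False
    rows, rejected = [], []
    for f, frame_df in snaps.df.groupby("frame", sort=True):
        resolved = {}
        missing = None
        for tag, sel in (("loop", loop_sel), ("site", site_sel)):
            for ch in chains:
                xyz, name = _resolve(frame_df, sel, ch)
                if xyz is None:
                    missing = f"{tag} atom {sel.atom_name} (res {sel.residue_index}) chain {ch}"
                    break
                resolved[(tag, ch)] = xyz
                prov_key = f"{tag}:{ch}"
                if provenance.setdefault(prov_key, name) != name:
                    provenance[prov_key] = "mixed"
                if name != sel.atom_name and not fallback_warned:
                    warnings.warn(
                        f"{tag} selector fell back to heavy atom {name!r}",
                        stacklevel=2,
                    )
                    fallback_warned = True
            if missing:
                break
        if missing:
            rejected.append((int(f), f"missing {missing}"))
            continue
        for lc in chains:
            for sc in chains:
                dx, dy, dz = resolved[("loop", lc)] - resolved[("site", sc)]
                d = float(np.sqrt(dx * dx + dy * dy + dz * dz))
                rows.append(
                    {
                        "frame": int(f),
                        "chain_pair": f"{lc}->{sc}",
                        "klass": "intra" if lc == sc else "inter",
                        "distance_A": d,
                    }
                )
    records = pd.DataFrame(rows, columns=["frame", "chain_pair", "klass", "distance_A"])
    return DistanceCensus(
        records=records,
        close_low=close_low,
        close_high=close_high,
        far_floor=far_floor,
        rejected_frames=rejected,
        selector_provenance=provenance,
    )


def close_fraction(
    census: DistanceCensus,
    klass: str,
    low: float = CLOSE_LOW_A,
    high: float = CLOSE_HIGH_A,
) -> float:
    """Fraction of ``klass`` distances in the half-open interval [low, high).

    Counted with exact rational arithmetic before conversion to float.
    """
    sub = census.records[census.records["klass"] == klass]
    if len(sub) == 0:
        raise ValueError(f"no records of class {klass!r}")
    d = sub["distance_A"].to_numpy()
    n_close = int(np.count_nonzero((d >= low) & (d < high)))
    return float(Fraction(n_close, len(sub)))


def min_class_distance(census: DistanceCensus, klass: str) -> float:
    """Exact minimum distance within one class."""
    sub = census.records[census.records["klass"] == klass]
    if len(sub) == 0:
        raise ValueError(f"no records of class {klass!r}")
    return float(sub["distance_A"].min())


def distance_histogram(
    census: DistanceCensus, klass: str, bin_width_A: float = 1.0
) -> pd.DataFrame:
    """Counts-vs-distance histogram for one class (left-closed bins)."""
    sub = census.records[census.records["klass"] == klass]
    if len(sub) == 0:
        raise ValueError(f"no records of class {klass!r}")
    d = sub["distance_A"].to_numpy()
    lo = np.floor(d.min() / bin_width_A) * bin_width_A
    hi = np.ceil(d.max() / bin_width_A) * bin_width_A + bin_width_A
    edges = np.arange(lo, hi + bin_width_A / 2, bin_width_A)
    counts, edges = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_left_A": edges[:-1], "bin_right_A": edges[1:], "count": counts}
    )
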