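"""Reading, validation and pairing of methyl peak-intensity tables.

A *peak table* is the raw observable of every stage downstream: one row per
assigned methyl resonance, holding the peak intensity and its baseplane-noise
uncertainty, optionally the 1H/13C chemical shifts, together with a metadata
block describing the sample (allosteric state, diamagnetic/paramagnetic,
cosolute identity, pH, salt, protein concentration).

Tables are plain text (TSV or CSV, header row, case-insensitive column names)
as exported from assignment software; no spectral processing happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleMeta",
    "PeakRecord",
    "PeakTable",
    "PairedPeaks",
    "PeakTableFormatError",
    "PeakTableValidationError",
    "PairingError",
    "read_peak_table",
    "write_peak_table",
    "read_sample_manifest",
    "pair_tables",
]

STATES = ("apo", "trp", "tyr")
MAGNETIC = ("diamagnetic", "paramagnetic")
COSOLUTES = ("none", "plus", "minus")

#: canonical column order for serialized tables
COLUMNS = [
    "residue_index",
    "residue_name",
    "methyl_id",
    "shift_H_ppm",
    "shift_C_ppm",
    "intensity",
    "noise_sigma",
]
REQUIRED_COLUMNS = ["residue_index", "methyl_id", "intensity", "noise_sigma"]


class PeakTableFormatError(ValueError):
    """Malformed input file (missing column, unparsable layout)."""


class PeakTableValidationError(ValueError):
    """Well-formed file whose content violates a table invariant."""


class PairingError(ValueError):
    """Two tables whose metadata make them incomparable."""


@dataclass(frozen=True)
class SampleMeta:
    """Sample condition attached to one peak table.

    ``evolution_delays_ms`` carries the ordered (Ta, Tb) delay pair for
    two-time-point rate data; ``covalent_label`` marks a spin label attached
    to the protein itself (as opposed to a paramagnetic cosolute).
    """

    state: str = "apo"
    magnetic: str = "diamagnetic"
    cosolute: str = "none"
    pH: float = 6.5
    nacl_mM: float = 150.0
    protein_conc_uM: float = 200.0
    construct: str = "WT"
    covalent_label: bool = False
    evolution_delays_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.magnetic not in MAGNETIC:
            raise ValueError(f"magnetic must be one of {MAGNETIC}, got {self.magnetic!r}")
        if self.cosolute not in COSOLUTES:
            raise ValueError(f"cosolute must be one of {COSOLUTES}, got {self.cosolute!r}")
        if self.magnetic == "paramagnetic" and self.cosolute == "none" and not self.covalent_label:
            raise ValueError(
                "paramagnetic sample requires a cosolute or a covalent spin label"
            )
        if not self.protein_conc_uM > 0:
            raise ValueError("protein_conc_uM must be > 0")
        if self.evolution_delays_ms is not None:
            ta, tb = self.evolution_delays_ms
            if not (tb > ta >= 0):
                raise ValueError("evolution delays require Tb > Ta >= 0")

    def compatible_for_pairing(self, other: "SampleMeta") -> bool:
        """True if the two samples differ only in magnetic/cosolute fields."""
        return (
            self.state == other.state
            and self.construct == other.construct
            and self.pH == other.pH
        )

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["evolution_delays_ms"] is not None:
            d["evolution_delays_ms"] = list(d["evolution_delays_ms"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SampleMeta":
        d = dict(d)
        delays = d.get("evolution_delays_ms")
        if delays is not None:
            d["evolution_delays_ms"] = tuple(float(x) for x in delays)
        return cls(**d)


@dataclass(frozen=True)
class PeakRecord:
    residue_index: int
    methyl_id: str
    intensity: float
    noise_sigma: float
    residue_name: str = ""
    shift_H_ppm: float = np.nan
    shift_C_ppm: float = np.nan

    def __post_init__(self) -> None:
        if not self.noise_sigma > 0:
            raise ValueError(f"noise_sigma must be > 0 ({self.methyl_id})")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0 ({self.methyl_id})")


@dataclass
class PeakTable:
    """One validated peak list plus its sample metadata.

    Records live in a :class:`pandas.DataFrame` with the canonical columns;
    the ``(residue_index, methyl_id)`` key is unique.
    """

    meta: SampleMeta
    df: pd.DataFrame
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise PeakTableValidationError("peak table must be non-empty")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise PeakTableFormatError(f"missing required column(s): {missing}")
        for c in COLUMNS:
            if c not in self.df.columns:
                self.df[c] = "" if c == "residue_name" else np.nan
        self.df = self.df[COLUMNS].reset_index(drop=True)
        self.df["residue_name"] = self.df["residue_name"].fillna("").astype(str)
        self.df["residue_index"] = self.df["residue_index"].astype(int)
        for c in ("shift_H_ppm", "shift_C_ppm", "intensity", "noise_sigma"):
            self.df[c] = self.df[c].astype(float)
        dup = self.df.duplicated(subset=["residue_index", "methyl_id"], keep=False)
        if dup.any():
            keys = sorted(set(self.df.loc[dup, "methyl_id"]))
            raise PeakTableValidationError(f"duplicate (residue, methyl) keys: {keys}")
        if (self.df["noise_sigma"] <= 0).any():
            bad = self.df.loc[self.df["noise_sigma"] <= 0, "methyl_id"].tolist()
            raise PeakTableValidationError(f"non-positive noise_sigma at {bad}")

    @property
    def records(self) -> list[PeakRecord]:
        return [
            PeakRecord(
                residue_index=int(r.residue_index),
                methyl_id=str(r.methyl_id),
                intensity=float(r.intensity),
                noise_sigma=float(r.noise_sigma),
                residue_name=str(r.residue_name) if pd.notna(r.residue_name) else "",
                shift_H_ppm=float(r.shift_H_ppm),
                shift_C_ppm=float(r.shift_C_ppm),
            )
            for r in self.df.itertuples(index=False)
        ]

    @classmethod
    def from_records(cls, meta: SampleMeta, records: Iterable[PeakRecord]) -> "PeakTable":
        rows = [
            {
                "residue_index": r.residue_index,
                "residue_name": r.residue_name,
                "methyl_id": r.methyl_id,
                "shift_H_ppm": r.shift_H_ppm,
                "shift_C_ppm": r.shift_C_ppm,
                "intensity": r.intensity,
                "noise_sigma": r.noise_sigma,
            }
            for r in records
        ]
        return cls(meta=meta, df=pd.DataFrame(rows))

    def keys(self) -> set[tuple[int, str]]:
        return set(zip(self.df["residue_index"], self.df["methyl_id"]))


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_peak_table(path: str | Path, meta: SampleMeta | str | Path) -> PeakTable:
    """Read one TSV/CSV peak table.

    ``meta`` is either a :class:`SampleMeta` or a path to a JSON/YAML sidecar
    holding one metadata block. Column names are matched case-insensitively;
    rows with non-numeric intensity are dropped with a row-level diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not isinstance(meta, SampleMeta):
        meta = SampleMeta.from_dict(_load_structured(Path(meta)))

    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, skipinitialspace=True,
                     float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {c.lower(): c for c in COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(
            f"{path.name}: missing required column(s): {missing}"
        )

    diagnostics: list[str] = []
    numeric = pd.to_numeric(df["intensity"], errors="coerce")
    bad = numeric.isna()
    for i in df.index[bad]:
        diagnostics.append(
            f"{path.name}: row {i + 2}: non-numeric intensity "
            f"{df.loc[i, 'intensity']!r} for {df.loc[i, 'methyl_id']}; row rejected"
        )
    df = df[~bad].copy()
    if len(df) == 0:
        raise PeakTableValidationError(f"{path.name}: no valid rows")
    df["intensity"] = numeric[~bad]
    df["residue_index"] = pd.to_numeric(df["residue_index"]).astype(int)
    df["noise_sigma"] = pd.to_numeric(df["noise_sigma"])
    for c in ("shift_H_ppm", "shift_C_ppm"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return PeakTable(meta=meta, df=df, diagnostics=diagnostics)


def write_peak_table(table: PeakTable, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a table as TSV; optionally a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if sidecar:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(table.meta.to_dict(), indent=1) + "\n"
        )


def _load_structured(path: Path) -> dict:
    text = Path(path).read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_sample_manifest(path: str | Path) -> dict[str, tuple[Path, SampleMeta]]:
    """Read a manifest mapping sample names to (table path, metadata) blocks.

    Format (YAML or JSON)::

        samples:
          dia: {path: dia.tsv, meta: {state: trp, magnetic: diamagnetic, ...}}
    """
    path = Path(path)
    doc = _load_structured(path)
    out = {}
    for name, block in doc["samples"].items():
        table_path = Path(block["path"])
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        out[name] = (table_path, SampleMeta.from_dict(block["meta"]))
    return out


@dataclass
class PairedPeaks:
    """Join of a diamagnetic and a paramagnetic table on (residue, methyl).

    ``pairs`` has suffixed intensity/noise columns; keys present in only one
    table are never dropped silently: they are listed in ``unmatched_dia`` /
    ``unmatched_para``. A key present in the diamagnetic but absent from the
    paramagnetic table is a *candidate bleached* peak (possible complete
    signal disappearance under strong PRE).
    """

    pairs: pd.DataFrame
    unmatched_dia: list[tuple[int, str]]
    unmatched_para: list[tuple[int, str]]
    meta_dia: SampleMeta
    meta_para: SampleMeta

    @property
    def candidate_bleached(self) -> list[tuple[int, str]]:
        return list(self.unmatched_dia)

    def counts_consistent(self, n_dia: int, n_para: int) -> bool:
        return n_dia + n_para == 2 * len(self.pairs) + len(self.unmatched_dia) + len(
            self.unmatched_para
        )


def pair_tables(dia: PeakTable, para: PeakTable) -> PairedPeaks:
    """Pair two validated tables on the (residue_index, methyl_id) key."""
    if not dia.meta.compatible_for_pairing(para.meta):
        raise PairingError(
            "cannot pair tables with different state/construct/pH: "
            f"{dia.meta.state}/{dia.meta.construct}/{dia.meta.pH} vs "
            f"{para.meta.state}/{para.meta.construct}/{para.meta.pH}"
        )
    key = ["residue_index", "methyl_id"]
    merged = dia.df.merge(para.df, on=key, how="outer", suffixes=("_dia", "_para"),
                          indicator=True)
    both = merged[merged["_merge"] == "both"].drop(columns="_merge")
    only_dia = merged[merged["_merge"] == "left_only"]
    only_para = merged[merged["_merge"] == "right_only"]
    return PairedPeaks(
        pairs=both.reset_index(drop=True),
        unmatched_dia=list(zip(only_dia["residue_index"], only_dia["methyl_id"])),
        unmatched_para=list(zip(only_para["residue_index"], only_para["methyl_id"])),
        meta_dia=dia.meta,
        meta_para=para.meta,
    )


def _replace_meta(table: PeakTable, **kwargs) -> PeakTable:
    """Return a copy of ``table`` with metadata fields replaced."""
    return PeakTable(meta=replace(table.meta, **kwargs), df=table.df.copy())
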