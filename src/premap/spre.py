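"""Solvent-PRE effective net charge mapping from dual charged cosolutes.

Two freely diffusing nitroxide cosolutes of opposite charge broaden methyl
peaks in proportion to how much they accumulate near each residue's patch of
protein surface.  Combining the two concentration-corrected intensity ratios
into one signed parameter,

    ϕ = I_ratio(−) − I_ratio(+)

gives a per-residue proxy for the near-surface charge sign: the negatively
charged cosolute concentrates at positively charged patches, so ϕ > 0 marks
a net positive region (and vice versa).  The uncertainty is the quadrature
sum σϕ = sqrt(σ₊² + σ₋²).

pH sensitivity is quantified as Δϕ = ϕ(pH 6.5) − ϕ(pH 7.5) per construct,
and divergence between two constructs as ΔΔϕ = |Δϕ(mutant) − Δϕ(wild-type)|,
with a two-part significance criterion: ΔΔϕ ≥ 0.4 and, in all four
underlying samples, σϕ ≤ 20% of |ϕ|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklist_io import PeakTable, SampleMeta
from .pre_core import build_pre_profile, DEFAULT_BLEACH_SNR

__all__ = [
    "PhiRecord",
    "PhiProfile",
    "SignificanceRecord",
    "phi",
    "phi_uncertainty",
    "build_phi_profile",
    "delta_phi",
    "significance_filter",
    "DDPHI_THRESHOLD",
    "SIGMA_FRACTION",
]

DDPHI_THRESHOLD = 0.4
SIGMA_FRACTION = 0.2

_CONVENTIONS = ("results", "methods")


def phi(ratio_minus: float, ratio_plus: float, convention: str = "results") -> float:
    """Signed effective net charge from the two cosolute intensity ratios.

    ``convention="results"`` (default): ϕ = ratio_minus − ratio_plus, so
    ϕ > 0 indicates a net positively charged region.  ``"methods"`` flips
    the sign.  Antisymmetric under swapping the cosolutes.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    val = float(ratio_minus) - float(ratio_plus)
    return val if convention == "results" else -val


def phi_uncertainty(sigma_ratio_plus: float, sigma_ratio_minus: float) -> float:
    """Quadrature propagation: sqrt(σ₊² + σ₋²)."""
    if sigma_ratio_plus < 0 or sigma_ratio_minus < 0:
        raise ValueError("sigmas must be >= 0")
    return math.hypot(sigma_ratio_plus, sigma_ratio_minus)


@dataclass(frozen=True)
class PhiRecord:
    residue_index: int
    methyl_id: str
    phi: float
    sigma_phi: float
    ratio_plus: float
    ratio_minus: float
    bleached_any: bool = False

    def __post_init__(self):
        if self.bleached_any and math.isfinite(self.phi):
            raise ValueError("phi is undefined when either cosolute peak is bleached")


@dataclass
class PhiProfile:
    """Per-residue effective net charge for one construct at one pH.

    ``df`` columns: residue_index, methyl_id, ratio_plus, ratio_minus,
    sigma_plus, sigma_minus, phi, sigma_phi, bleached_any.  Residues bleached
    under either cosolute carry NaN ϕ and are flagged, never dropped.
    """

    meta: SampleMeta
    df: pd.DataFrame
    convention: str = "results"


def build_phi_profile(
    dia: PeakTable,
    plus: PeakTable,
    minus: PeakTable,
    *,
    convention: str = "results",
    bleach_snr_threshold: float = DEFAULT_BLEACH_SNR,
) -> PhiProfile:
    """Compute ϕ per residue from the three-sample solvent-PRE design.

    ``dia`` is the cosolute-free reference, ``plus``/``minus`` the samples
    with positively/negatively charged cosolute.  Each cosolute ratio is the
    concentration-corrected PRE ratio against the shared diamagnetic table.
    """
    prof_plus = build_pre_profile(dia, plus, bleach_snr_threshold)
    prof_minus = build_pre_profile(dia, minus, bleach_snr_threshold)
    key = ["residue_index", "methyl_id"]
    p = prof_plus.df.set_index(key)
    m = prof_minus.df.set_index(key)
    shared = p.index.intersection(m.index)
    if len(shared) == 0:
        raise ValueError("cosolute profiles share no keys")
    rows = []
    for idx in shared:
        rp, rm = p.loc[idx], m.loc[idx]
        bleached = bool(rp["bleached"]) or bool(rm["bleached"])
        rows.append(
            {
                "residue_index": idx[0],
                "methyl_id": idx[1],
                "ratio_plus": float(rp["i_ratio"]),
                "ratio_minus": float(rm["i_ratio"]),
                "sigma_plus": float(rp["sigma_ratio"]),
                "sigma_minus": float(rm["sigma_ratio"]),
                "phi": np.nan
                if bleached
                else phi(rm["i_ratio"], rp["i_ratio"], convention),
                "sigma_phi": np.nan
                if bleached
                else phi_uncertainty(rp["sigma_ratio"], rm["sigma_ratio"]),
                "bleached_any": bleached,
            }
        )
    df = pd.DataFrame(rows).sort_values(key).reset_index(drop=True)
    return PhiProfile(meta=dia.meta, df=df, convention=convention)


def delta_phi(profile_65: PhiProfile, profile_75: PhiProfile) -> pd.DataFrame:
    """Per-residue pH difference Δϕ = ϕ(pH 6.5) − ϕ(pH 7.5).

    Returns a frame with columns residue_index, methyl_id, delta_phi,
    sigma_delta_phi, excluded, reason.  Residues bleached (or absent) at
    either pH are excluded with a reason, never silently dropped.
    """
    key = ["residue_index", "methyl_id"]
    a = profile_65.df.set_index(key)
    b = profile_75.df.set_index(key)
    all_keys = a.index.union(b.index)
    if len(a.index.intersection(b.index)) == 0:
        raise ValueError("profiles share no keys")
    rows = []
    for idx in all_keys:
        in_a, in_b = idx in a.index, idx in b.index
        reason = None
        if not (in_a and in_b):
            reason = "missing at pH 6.5" if not in_a else "missing at pH 7.5"
        else:
            ra, rb = a.loc[idx], b.loc[idx]
            if bool(ra["bleached_any"]) or bool(rb["bleached_any"]):
                reason = "bleached at one pH"
        if reason is not None:
            rows.append(
                {
                    "residue_index": idx[0],
                    "methyl_id": idx[1],
                    "delta_phi": np.nan,
                    "sigma_delta_phi": np.nan,
                    "excluded": True,
                    "reason": reason,
                }
            )
        else:
            rows.append(
                {
                    "residue_index": idx[0],
                    "methyl_id": idx[1],
                    "delta_phi": float(ra["phi"] - rb["phi"]),
                    "sigma_delta_phi": float(np.hypot(ra["sigma_phi"], rb["sigma_phi"])),
                    "excluded": False,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows).sort_values(key).reset_index(drop=True)


@dataclass(frozen=True)
class SignificanceRecord:
    residue_index: int
    delta_phi_wt: float
    delta_phi_mut: float
    ddphi: float
    passes_ddphi: bool
    passes_sigma_filter: bool

    @property
    def significant(self) -> bool:
        return self.passes_ddphi and self.passes_sigma_filter


def _phi_by_residue(profile: PhiProfile) -> pd.DataFrame:
    """Collapse a profile to one (ϕ, σϕ) per residue index.

    Methyl peaks of one residue are alternate probes of the same surface
    patch; where a residue carries several, the minimum-variance (smallest
    σϕ) peak is taken.
    """
    df = profile.df[~profile.df["bleached_any"]].copy()
    df = df.sort_values("sigma_phi").drop_duplicates("residue_index", keep="first")
    return df.set_index("residue_index")[["phi", "sigma_phi"]]


def significance_filter(
    wt_65: PhiProfile,
    wt_75: PhiProfile,
    mut_65: PhiProfile,
    mut_75: PhiProfile,
    ddphi_threshold: float = DDPHI_THRESHOLD,
    sigma_fraction: float = SIGMA_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the divergence criterion between two constructs.

    A residue is *significant* iff

    * ΔΔϕ = |Δϕ(mut) − Δϕ(wt)| ≥ ``ddphi_threshold``, and
    * in all four samples (two constructs × two pHs) σϕ ≤
      ``sigma_fraction``·|ϕ|.

    Returns ``(records, exclusions)``: a per-residue audit frame with
    columns residue_index, phi/sigma for the four samples, delta_phi_wt,
    delta_phi_mut, ddphi, passes_ddphi, passes_sigma_filter, significant;
    and an exclusion frame for residues missing any of the four samples.
    """
    samples = {
        "wt_65": _phi_by_residue(wt_65),
        "wt_75": _phi_by_residue(wt_75),
        "mut_65": _phi_by_residue(mut_65),
        "mut_75": _phi_by_residue(mut_75),
    }
    all_res = sorted(set().union(*(set(s.index) for s in samples.values())))
    rows, excl = [], []
    for res in all_res:
        missing = [name for name, s in samples.items() if res not in s.index]
        if missing:
            excl.append(
                {"residue_index": res, "reason": f"missing samples: {', '.join(missing)}"}
            )
            continue
        vals = {name: s.loc[res] for name, s in samples.items()}
        d_wt = float(vals["wt_65"]["phi"] - vals["wt_75"]["phi"])
        d_mut = float(vals["mut_65"]["phi"] - vals["mut_75"]["phi"])
        ddphi = abs(d_mut - d_wt)
        passes_sigma = all(
            v["sigma_phi"] <= sigma_fraction * abs(v["phi"]) for v in vals.values()
        )
        passes_dd = ddphi >= ddphi_threshold
        row = {"residue_index": res}
        for name, v in vals.items():
            row[f"phi_{name}"] = float(v["phi"])
            row[f"sigma_phi_{name}"] = float(v["sigma_phi"])
        row.update(
            {
                "delta_phi_wt": d_wt,
                "delta_phi_mut": d_mut,
                "ddphi": ddphi,
                "passes_ddphi": passes_dd,
                "passes_sigma_filter": passes_sigma,
                "significant": passes_dd and passes_sigma,
            }
        )
        rows.append(row)
    records = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["residue_index", "reason"])
    return records, exclusions
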