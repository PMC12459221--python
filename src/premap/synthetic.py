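"""Synthetic forward models: the ground truth behind every recovery test.

Three generators emulate the statistical structure the analysis stages
assume, so each stage can be verified by parameter recovery:

* **PRE peak tables** from a weighted conformational ensemble of spin-label
  positions.  The PRE rate at a probe is Γ₂ = K · Σᵢ wᵢ rᵢ⁻⁶ (fast-exchange
  population-weighted ⟨r⁻⁶⟩; the full Solomon–Bloembergen prefactor is
  lumped into one calibratable constant K).  Peak intensities decay as
  I_para = I₀·exp(−Γ₂·t)/c with Gaussian baseplane noise.
* **Solvent-PRE tables** from a per-residue signed surface-charge parameter
  ψ, with Boltzmann-like cosolute coupling: the negatively charged cosolute
  is enriched at positive patches, Γ₂(−) = Γ₂⁰·exp(+κψ), Γ₂(+) =
  Γ₂⁰·exp(−κψ).
* **Dimer snapshot sets** with a planted fraction of inter-protomer close
  approaches, realized as explicit 3D coordinates on two chains so the
  distance census *measures* (never reads) the planted distances.

The default K is calibrated to the ~25 Å nitroxide observability ceiling:
Γ₂(25 Å)·t = 0.05, i.e. ≈5% attenuation at the edge of detectability.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklist_io import PeakRecord, PeakTable, SampleMeta
from .md_distances import SnapshotSet
from .spre import PhiProfile

__all__ = [
    "LoopEnsembleModel",
    "SurfaceChargeModel",
    "DEFAULT_EVOLUTION_TIME_S",
    "DETECTION_CEILING_A",
    "default_pre_scale_K",
    "gamma2_from_ensemble",
    "two_point_intensities",
    "generate_pre_tables",
    "generate_spre_tables",
    "generate_snapshots",
    "make_significance_fixture",
    "SIGNIFICANT_RESIDUES",
]

DEFAULT_EVOLUTION_TIME_S = 0.010
DETECTION_CEILING_A = 25.0
#: attenuation Γ₂·t at the detection ceiling used to calibrate K
_CEILING_ATTENUATION = 0.05


def default_pre_scale_K(evolution_time_s: float = DEFAULT_EVOLUTION_TIME_S) -> float:
    """Lumped PRE prefactor K (Å⁶·s⁻¹) calibrated to the 25 Å ceiling."""
    return _CEILING_ATTENUATION * DETECTION_CEILING_A**6 / evolution_time_s


@dataclass
class LoopEnsembleModel:
    """Two-(or n-)population spin-label ensemble with fixed methyl probes.

    ``members``: (N, 3) label positions in Å with ``weights`` summing to 1.
    ``probe_sites``: (residue_index, methyl_id) → 3D probe position.
    """

    members: np.ndarray
    weights: np.ndarray
    probe_sites: dict[tuple[int, str], np.ndarray]
    pre_scale_K: float = field(default_factory=default_pre_scale_K)
    evolution_time_s: float = DEFAULT_EVOLUTION_TIME_S
    base_intensity: float = 1000.0
    noise_sigma: float = 20.0
    rng_seed: int = 0

    def __post_init__(self):
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("ensemble weights must sum to 1")
        if not self.pre_scale_K > 0:
            raise ValueError("pre_scale_K must be > 0")
        if not np.isfinite(self.members).all():
            raise ValueError("member positions must be finite")


def gamma2_from_ensemble(model: LoopEnsembleModel, probe: tuple[int, str]) -> float:
    """Γ₂ = K · Σᵢ wᵢ rᵢ⁻⁶ for one probe site (s⁻¹)."""
    site = np.asarray(model.probe_sites[probe], dtype=float)
    r = np.linalg.norm(model.members - site, axis=1)
    if np.any(r == 0):
        raise ValueError(f"spin-label member coincides with probe {probe}")
    return float(model.pre_scale_K * np.sum(model.weights * r**-6))


def two_point_intensities(
    gamma2_per_s: float,
    ta_s: float,
    tb_s: float,
    *,
    r2_dia_per_s: float = 20.0,
    base_intensity: float = 1000.0,
) -> tuple[float, float, float, float]:
    """Noiseless (I_para_Ta, I_para_Tb, I_dia_Ta, I_dia_Tb).

    Exponential decay with a shared diamagnetic baseline rate; the exact
    forward model inverted by the two-time-point Γ₂ estimate.
    """
    ida = base_intensity * np.exp(-r2_dia_per_s * ta_s)
    idb = base_intensity * np.exp(-r2_dia_per_s * tb_s)
    ipa = base_intensity * np.exp(-(r2_dia_per_s + gamma2_per_s) * ta_s)
    ipb = base_intensity * np.exp(-(r2_dia_per_s + gamma2_per_s) * tb_s)
    return float(ipa), float(ipb), float(ida), float(idb)


def _probe_record(residue_index, methyl_id, intensity, noise_sigma):
    return PeakRecord(
        residue_index=residue_index,
        methyl_id=methyl_id,
        intensity=float(max(intensity, 0.0)),  # spectra cannot go negative
        noise_sigma=float(max(noise_sigma, 1e-9)),
    )


def generate_pre_tables(
    model: LoopEnsembleModel,
    c_true: float = 1.0,
    seed: int | None = None,
    state: str = "trp",
) -> tuple[PeakTable, PeakTable, pd.DataFrame]:
    """Forward-simulate one diamagnetic/paramagnetic peak-table pair.

    I_dia = I₀ + ε,  I_para = I₀·exp(−Γ₂·t)/c_true + ε,  ε ~ N(0, σ²),
    clipped at zero.  The paramagnetic metadata carries a protein
    concentration ``c_true`` times the diamagnetic one, so the analysis must
    recover the concentration correction from metadata alone.  Returns
    (dia, para, truth); truth columns: residue_index, methyl_id,
    gamma2_true_per_s, ratio_true, clipped.
    """
    rng = np.random.default_rng(seed if seed is not None else model.rng_seed)
    dia_recs, para_recs, truth = [], [], []
    for (res, methyl), _site in model.probe_sites.items():
        g2 = gamma2_from_ensemble(model, (res, methyl))
        i_dia = model.base_intensity + rng.normal(0.0, model.noise_sigma or 0.0)
        i_para_clean = model.base_intensity * np.exp(-g2 * model.evolution_time_s) / c_true
        i_para = i_para_clean + rng.normal(0.0, model.noise_sigma or 0.0)
        dia_recs.append(_probe_record(res, methyl, i_dia, model.noise_sigma))
        para_recs.append(_probe_record(res, methyl, i_para, model.noise_sigma))
        truth.append(
            {
                "residue_index": res,
                "methyl_id": methyl,
                "gamma2_true_per_s": g2,
                "ratio_true": float(np.exp(g2 * model.evolution_time_s)),
                "clipped": bool(i_para < 0 or i_dia < 0),
            }
        )
    conc_dia = 200.0
    meta_dia = SampleMeta(
        state=state, magnetic="diamagnetic", protein_conc_uM=conc_dia,
        construct="S220C-TEMPO",
    )
    meta_para = SampleMeta(
        state=state, magnetic="paramagnetic", covalent_label=True,
        protein_conc_uM=conc_dia * c_true, construct="S220C-TEMPO",
    )
    return (
        PeakTable.from_records(meta_dia, dia_recs),
        PeakTable.from_records(meta_para, para_recs),
        pd.DataFrame(truth),
    )


@dataclass
class SurfaceChargeModel:
    """Per-residue signed near-surface charge parameters ψ.

    ``psi``: residue_index → ψ (dimensionless, sign = surface charge sign).
    ``cosolute_coupling`` κ > 0 sets how strongly a cosolute of opposite
    charge is enriched: Γ₂(∓) = Γ₂⁰·exp(±κψ).
    """

    psi: dict[int, float]
    cosolute_coupling: float = 1.0
    base_gamma2_per_s: float = 5.0
    evolution_time_s: float = DEFAULT_EVOLUTION_TIME_S
    base_intensity: float = 1000.0
    noise_sigma: float = 20.0

    def __post_init__(self):
        if not self.cosolute_coupling > 0:
            raise ValueError("cosolute_coupling must be > 0")
        if not all(np.isfinite(v) for v in self.psi.values()):
            raise ValueError("psi must be finite")


def generate_spre_tables(
    model: SurfaceChargeModel,
    seed: int = 0,
    construct: str = "WT",
    pH: float = 6.5,
) -> tuple[PeakTable, PeakTable, PeakTable, pd.DataFrame]:
    """Forward-simulate the three-sample solvent-PRE design.

    Returns (dia, plus, minus, truth): a cosolute-free reference and the two
    charged-cosolute samples, all at equal protein concentration.  Truth
    columns: residue_index, methyl_id, psi, gamma2_plus_per_s,
    gamma2_minus_per_s, phi_true (under the ϕ = ratio₋ − ratio₊
    convention).
    """
    rng = np.random.default_rng(seed)
    t = model.evolution_time_s
    dia_recs, plus_recs, minus_recs, truth = [], [], [], []
    for res in sorted(model.psi):
        psi = model.psi[res]
        methyl = f"R{res}-m1"
        g2_minus = model.base_gamma2_per_s * np.exp(+model.cosolute_coupling * psi)
        g2_plus = model.base_gamma2_per_s * np.exp(-model.cosolute_coupling * psi)
        i_dia = model.base_intensity + rng.normal(0.0, model.noise_sigma or 0.0)
        i_plus = model.base_intensity * np.exp(-g2_plus * t) + rng.normal(
            0.0, model.noise_sigma or 0.0
        )
        i_minus = model.base_intensity * np.exp(-g2_minus * t) + rng.normal(
            0.0, model.noise_sigma or 0.0
        )
        dia_recs.append(_probe_record(res, methyl, i_dia, model.noise_sigma))
        plus_recs.append(_probe_record(res, methyl, i_plus, model.noise_sigma))
        minus_recs.append(_probe_record(res, methyl, i_minus, model.noise_sigma))
        truth.append(
            {
                "residue_index": res,
                "methyl_id": methyl,
                "psi": psi,
                "gamma2_plus_per_s": float(g2_plus),
                "gamma2_minus_per_s": float(g2_minus),
                "phi_true": float(np.exp(g2_minus * t) - np.exp(g2_plus * t)),
            }
        )
    common = dict(state="trp", pH=pH, construct=construct, protein_conc_uM=200.0)
    meta_dia = SampleMeta(magnetic="diamagnetic", cosolute="none", **common)
    meta_plus = SampleMeta(magnetic="paramagnetic", cosolute="plus", **common)
    meta_minus = SampleMeta(magnetic="paramagnetic", cosolute="minus", **common)
    return (
        PeakTable.from_records(meta_dia, dia_recs),
        PeakTable.from_records(meta_plus, plus_recs),
        PeakTable.from_records(meta_minus, minus_recs),
        pd.DataFrame(truth),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion draw."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_snapshots(
    n_frames: int = 600,
    f_close_inter: float = 0.08,
    close_range: tuple[float, float] = (5.0, 15.0),
    far_range: tuple[float, float] = (25.0, 45.0),
    seed: int = 0,
    frame_interval_ns: float = 1.0,
    site_separation_A: float = 30.0,
) -> tuple[SnapshotSet, pd.DataFrame]:
    """Dimer snapshot frames with a planted inter-protomer close fraction.

    Each frame carries four atoms: a loop reference atom (SER 220 HG) and an
    active-site reference atom (VAL 197 HG11) on each of chains A and B.
    The two inter-protomer distances (loop A→site B, loop B→site A) are
    independently *close* (uniform in ``close_range``) with probability
    ``f_close_inter``, else uniform in ``far_range``; both intra-protomer
    distances are uniform in ``far_range``.  The four planted distances are
    realized exactly as 3D geometry (the site atoms sit
    ``site_separation_A`` apart; triangle feasibility truncates an intra
    draw to [far_low, site_separation + d_inter] when its partner inter
    distance is close) and each frame gets a random rigid rotation +
    translation.  Returns (snapshots, truth); truth columns: frame,
    d_AA, d_AB, d_BA, d_BB, close_AB, close_BA.
    """
    if not 0.0 <= f_close_inter <= 1.0:
        raise ValueError("f_close_inter must be in [0, 1]")
    if close_range[1] > far_range[0]:
        raise ValueError("close_range and far_range must be disjoint (close below far)")
    rng = np.random.default_rng(seed)
    L = site_separation_A
    rows, truth = [], []

    def draw_inter():
        close = bool(rng.random() < f_close_inter)
        lo, hi = close_range if close else far_range
        return close, float(rng.uniform(lo, hi))

    def draw_intra(d_inter):
        hi = min(far_range[1], L + d_inter)
        return float(rng.uniform(far_range[0], hi))

    for f in range(n_frames):
        close_ab, d_ab = draw_inter()
        close_ba, d_ba = draw_inter()
        d_aa = draw_intra(d_ab)
        d_bb = draw_intra(d_ba)

        site_a = np.zeros(3)
        site_b = np.array([L, 0.0, 0.0])
        # loop A: distance d_aa to site A, d_ab to site B; placed in xy-plane
        x = (d_aa**2 - d_ab**2 + L**2) / (2 * L)
        y = np.sqrt(max(d_aa**2 - x**2, 0.0))
        loop_a = np.array([x, y, 0.0])
        # loop B: distance d_ba to site A (inter), d_bb to site B (intra); xz-plane
        x = (d_ba**2 - d_bb**2 + L**2) / (2 * L)
        z = np.sqrt(max(d_ba**2 - x**2, 0.0))
        loop_b = np.array([x, 0.0, z])

        rot = _random_rotation(rng)
        shift = rng.uniform(-50.0, 50.0, size=3)
        atoms = {
            ("A", 220, "HG"): loop_a,
            ("A", 197, "HG11"): site_a,
            ("B", 220, "HG"): loop_b,
            ("B", 197, "HG11"): site_b,
        }
        for (chain, res, name), xyz in atoms.items():
            p = rot @ xyz + shift
            rows.append((f, chain, res, name, p[0], p[1], p[2]))
        truth.append(
            {
                "frame": f,
                "d_AA": d_aa,
                "d_AB": d_ab,
                "d_BA": d_ba,
                "d_BB": d_bb,
                "close_AB": close_ab,
                "close_BA": close_ba,
            }
        )
    df = pd.DataFrame(
        rows, columns=["frame", "chain", "residue_index", "atom_name", "x", "y", "z"]
    )
    return (
        SnapshotSet(df=df, frame_interval_ns=frame_interval_ns),
        pd.DataFrame(truth),
    )


# ---------------------------------------------------------------------------
# Backward-constructed significance fixture
# ---------------------------------------------------------------------------

#: residues planted to pass the ΔΔϕ ≥ 0.4 + σ ≤ 20% filter (one-letter code, index)
SIGNIFICANT_RESIDUES = {
    ("L", 12), ("L", 19), ("L", 104), ("V", 185), ("I", 201),
    ("V", 211), ("V", 214), ("I", 237), ("V", 238), ("L", 251),
}

#: decoys failing exactly one criterion each
_DECOYS_SMALL_DDPHI = [("V", 20), ("I", 31), ("V", 120), ("V", 197), ("I", 225)]
_DECOYS_SIGMA_FAIL = [("L", 205), ("L", 230), ("I", 233), ("I", 128), ("I", 129)]


def _phi_profile_from_values(values: dict[int, tuple[str, float, float]],
                             meta: SampleMeta) -> PhiProfile:
    """Build a PhiProfile directly from per-residue (code, ϕ, σϕ) values.

    Ratios are reconstructed consistently with ϕ = ratio₋ − ratio₊ with
    ratio₊ pinned at 1 (a cosolute-transparent reference).
    """
    rows = []
    for res, (code, phi_val, sigma) in sorted(values.items()):
        rows.append(
            {
                "residue_index": res,
                "methyl_id": f"{code}{res}-m1",
                "ratio_plus": 1.0,
                "ratio_minus": 1.0 + phi_val,
                "sigma_plus": sigma / np.sqrt(2.0),
                "sigma_minus": sigma / np.sqrt(2.0),
                "phi": phi_val,
                "sigma_phi": sigma,
                "bleached_any": False,
            }
        )
    return PhiProfile(meta=meta, df=pd.DataFrame(rows), convention="results")


def make_significance_fixture(
    ddphi_pass: float = 0.6,
    ddphi_fail: float = 0.1,
    sigma_ok_fraction: float = 0.1,
    sigma_bad_fraction: float = 0.25,
) -> tuple[PhiProfile, PhiProfile, PhiProfile, PhiProfile, set[int]]:
    """Four ϕ profiles constructed backward from the significance criterion.

    Exactly the :data:`SIGNIFICANT_RESIDUES` pass both filters; half the
    decoys fail the ΔΔϕ threshold (ΔΔϕ = ``ddphi_fail``) and half fail the
    σ filter in one of the four samples (σϕ = ``sigma_bad_fraction``·|ϕ|).
    Returns (wt_65, wt_75, mut_65, mut_75, expected_significant_indices).
    """
    wt65, wt75, mut65, mut75 = {}, {}, {}, {}

    def plant(code, res, ddphi, bad_sigma_sample=None):
        # mild per-residue variation so the fixture is not a constant table
        base = 1.0 + 0.05 * (res % 7)
        d_wt = 0.2
        d_mut = d_wt + ddphi  # ΔΔϕ = |d_mut − d_wt| = ddphi exactly
        phis = {
            "wt_65": base + d_wt,
            "wt_75": base,
            "mut_65": base + d_mut,
            "mut_75": base,
        }
        for sample, target in (("wt_65", wt65), ("wt_75", wt75),
                               ("mut_65", mut65), ("mut_75", mut75)):
            frac = sigma_bad_fraction if sample == bad_sigma_sample else sigma_ok_fraction
            target[res] = (code, phis[sample], frac * abs(phis[sample]))

    for code, res in sorted(SIGNIFICANT_RESIDUES, key=lambda t: t[1]):
        plant(code, res, ddphi_pass)
    for code, res in _DECOYS_SMALL_DDPHI:
        plant(code, res, ddphi_fail)
    for i, (code, res) in enumerate(_DECOYS_SIGMA_FAIL):
        bad = ("wt_65", "wt_75", "mut_65", "mut_75")[i % 4]
        plant(code, res, ddphi_pass, bad_sigma_sample=bad)

    metas = {
        ("WT", 6.5): SampleMeta(state="trp", construct="WT", pH=6.5),
        ("WT", 7.5): SampleMeta(state="trp", construct="WT", pH=7.5),
        ("D215A", 6.5): SampleMeta(state="trp", construct="D215A", pH=6.5),
        ("D215A", 7.5): SampleMeta(state="trp", construct="D215A", pH=7.5),
    }
    return (
        _phi_profile_from_values(wt65, metas[("WT", 6.5)]),
        _phi_profile_from_values(wt75, metas[("WT", 7.5)]),
        _phi_profile_from_values(mut65, metas[("D215A", 6.5)]),
        _phi_profile_from_values(mut75, metas[("D215A", 7.5)]),
        {res for _, res in SIGNIFICANT_RESIDUES},
    )
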