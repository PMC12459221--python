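# premap

Quantitative NMR and simulation analysis of a flexible allosteric loop:
paramagnetic relaxation enhancement (PRE) intensity-ratio profiling,
two-time-point Γ₂ rates, dual-cosolute solvent-PRE effective net charge
mapping, methyl chemical-shift perturbations, and an inter-/intra-protomer
distance census over molecular-dynamics snapshots — plus forward models that
generate every input with known ground truth, so each analysis stage is
verified by parameter recovery.

## The problem

Chorismate mutase (CM), a homodimeric enzyme of the shikimate pathway, is
allosterically activated by tryptophan and inhibited by tyrosine. A long
flexible loop between helices 11 and 12 (residues 212–226), invisible in
crystal structures and NMR spectra, modulates the enzyme's activity from
~20 Å away. Because the loop cannot be observed directly, its behaviour is
read out indirectly:

* a nitroxide spin label placed in the loop broadens methyl peaks of
  residues the loop approaches (PRE, ~r⁻⁶ distance dependence, observable
  to ~25 Å);
* two solvent cosolutes of opposite charge report per-residue near-surface
  electrostatics through differential solvent-PRE broadening;
* simulation snapshots of the dimer resolve whether loop–active-site
  contacts are within one protomer or across the dimer interface.

`premap` implements the full quantitative pipeline behind these readouts.

## The statistics at its core

Per methyl peak, with diamagnetic intensity *I*_dia, paramagnetic intensity
*I*_para and concentration correction *c* = [P]_para/[P]_dia:

    I_ratio = I_dia / (I_para · c)
    σ_ratio = I_ratio · √((σ_dia/I_dia)² + (σ_para/I_para)²)

Peaks broadened below a 3σ detection floor are *bleached* and carried as
lower bounds, never as point estimates. With intensities at two evolution
delays T_a < T_b, the PRE rate follows exactly from two-point inversion:

    Γ₂ = ln[(I_dia(T_b)·I_para(T_a)) / (I_dia(T_a)·I_para(T_b))] / (T_b − T_a)

For the solvent-PRE charge map, with intensity ratios under the negatively
(−) and positively (+) charged cosolute:

    ϕ = I_ratio(−) − I_ratio(+),     σ_ϕ = √(σ₊² + σ₋²)

so ϕ > 0 marks a net positively charged surface patch. pH sensitivity is
Δϕ = ϕ(pH 6.5) − ϕ(pH 7.5) per construct, construct divergence is
ΔΔϕ = |Δϕ(mutant) − Δϕ(wild type)|, and a residue is significant when
ΔΔϕ ≥ 0.4 **and** σ_ϕ ≤ 0.2·|ϕ| in all four samples. Chemical-shift
perturbations use the two-nucleus form CSP = √(Δδ_H² + (0.133·Δδ_C)²).
The distance census classifies the four loop↔active-site chain pairings per
frame (A→A, B→B intra; A→B, B→A inter) against a [5, 15) Å close-approach
window and a 25 Å intra-protomer floor.

## Worked example

The numbered scripts under `analysis/` run the whole story on synthetic
data with planted ground truth (inputs under `scratch/data/`, report tables
under `results/tables/`):

```sh
python analysis/01_simulate.py
python analysis/02_pre_profiles.py
python analysis/03_spre_charge.py
python analysis/04_csp.py
python analysis/05_distance_census.py
```

`02_pre_profiles.py` prints:

```
trp: 14 probes, max ratio 5.69 at V214-g1 (group proximal_group1), max |ratio - truth| = 0.870
tyr: 14 probes, max ratio 3.86 at V214-g1 (group proximal_group1), max |ratio - truth| = 0.394
largest ΔI (Trp − Tyr):
  V197-g1: ΔI = +4.06 ± 0.53
  V20-g1: ΔI = +1.85 ± 0.18
  V214-g1: ΔI = +1.83 ± 0.73
```

The planted 8%-occupancy loop excursion toward the active-site face is
invisible in the Tyr-state profile but dominates the Trp−Tyr difference at
the active-site probes V197 and V20 — a transient sub-population detected
through ⟨r⁻⁶⟩-weighted PRE. `03_spre_charge.py` recovers exactly the ten
residues planted to gain positive surface charge in the mutant at low pH:

```
D215A: mean |Δϕ(pH 6.5 − 7.5)| = 0.79 over 20 residues
significant divergence (ΔΔϕ ≥ 0.4, σ filter): [12, 19, 104, 185, 201, 211, 214, 237, 238, 251]
```

and `05_distance_census.py` measures the planted interprotomer contact
fraction from explicit 3D coordinates:

```
trp: inter close fraction 8.00% (planted 8.00%, n = 1200); min intra = 25.0 Å; min inter = 5.1 Å
tyr: inter close fraction 0.42% (planted 0.42%, n = 1200); min intra = 25.0 Å; min inter = 5.9 Å
```

A `premap` console command exposes the same stages on user-supplied tables
(`premap pre-profile`, `premap gamma2`, `premap spre-phi`, `premap csp`,
`premap md-dist`, `premap simulate`, `premap run`); see `premap --help`.

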