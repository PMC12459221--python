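# Methods

## Measurement model

A nitroxide spin label attached in the flexible loop accelerates transverse
relaxation of nearby methyl ¹H spins. Over one evolution period *t* the
paramagnetic peak intensity is attenuated by exp(−Γ₂·t) relative to the
diamagnetic reference, so the concentration-corrected intensity ratio
I_ratio = I_dia/(I_para·c) estimates exp(Γ₂·t) ≥ 1; larger ratios mean a
shorter (population-averaged) label–methyl distance. The concentration
correction c is the paramagnetic-over-diamagnetic protein concentration
ratio taken from sample metadata and treated as error-free: only baseplane
intensity noise is propagated, to first order,

σ_ratio = I_ratio·√((σ_dia/I_dia)² + (σ_para/I_para)²).

The propagation is linear in the noise; a Monte-Carlo check (10⁵ draws)
shows agreement within a few percent for σ/I ≤ 0.1, which is the regime the
tests and acceptance script enforce. Beyond σ/I ≈ 0.1 the 1/I_para
nonlinearity inflates the true spread and the first-order formula
underestimates it — one reason bleached peaks are never assigned a numeric
σ.

**Bleached peaks.** A paramagnetic peak below `bleach_snr_threshold` (3 by
default) times its noise σ is flagged bleached. Its ratio is stored as the
lower bound obtained by evaluating the ratio at that floor, with a
`is_lower_bound` flag; it never enters numeric differences. Diamagnetic-only
keys (the peak vanished entirely from the paramagnetic spectrum) are
treated the same way, with the floor taken from the paramagnetic table's
median noise. The 3σ default is a conventional detection limit; it is a
config parameter, not a fitted value.

**Two-point Γ₂.** When intensities exist at two delays T_a < T_b with a
shared diamagnetic baseline rate, Γ₂ = ln[(I_dia(T_b)·I_para(T_a)) /
(I_dia(T_a)·I_para(T_b))]/(T_b−T_a) is the exact algebraic inverse of
two-point exponential decay — no fitting, no initialization. The tests
verify machine-precision recovery for planted rates across [0, 200] s⁻¹.
Intensities at or below a supplied noise floor are clipped to the floor and
the result flagged as a lower bound (the decay may have been faster than
observable).

**Effector differences.** ΔI = I_ratio(state a) − I_ratio(state b) on
shared, unbleached keys with quadrature σ. If one side is bleached the
record is sign-only: a lower bound minus a finite value fixes the sign of
the difference but not its magnitude. Proximal/distal group labels are a
configured annotation (the label's neighbourhood vs. the excursion-reporting
distal set), deliberately not a clustering: group membership is a scientific
statement about geometry, not a property of one noisy dataset.

## Solvent-PRE effective net charge

Two freely diffusing TEMPO-like cosolutes of opposite charge produce
solvent PREs proportional to their local accumulation. Each cosolute sample
is ratioed against a shared cosolute-free reference, and
ϕ = I_ratio(−) − I_ratio(+). A negatively charged cosolute concentrates at
positively charged patches, so ϕ > 0 ⇔ net positive surface. Both sign
orders appear in the literature for this combination; this package defaults
to the convention above (the only one consistent with "larger ratio =
stronger PRE") and exposes it as `convention="results"|"methods"`.

σ_ϕ = √(σ₊² + σ₋²) ignores the correlation induced by the shared
diamagnetic reference; the Monte-Carlo comparison in the tests (which
simulates the shared reference explicitly) shows the approximation is good
to a few percent at the noise levels used, because the reference peak is
the least-attenuated and contributes the smallest relative noise.

**Significance filter.** Per residue, Δϕ = ϕ(pH 6.5) − ϕ(pH 7.5) for each
construct, ΔΔϕ = |Δϕ(mut) − Δϕ(wt)|, and significance requires ΔΔϕ ≥ 0.4
together with σ_ϕ ≤ 0.2·|ϕ| in all four construct × pH samples. The 20%
rule is applied to |ϕ| so it is well defined for negative charges. Residues
with several methyl peaks are collapsed to the minimum-σ peak before
filtering (alternate probes of the same surface patch). Residues missing
any of the four samples, or bleached under either cosolute, are excluded
with an explicit reason — never silently dropped. The filter is monotone in
the ΔΔϕ threshold by construction.

## Chemical-shift perturbation

CSP = √(Δδ_H² + (α·Δδ_C)²) with α = 0.133, the standard methyl two-nucleus
quadrature with the ¹³C axis scaled to the ¹H shift dispersion. No built-in
significance cutoff is claimed; reports rank CSPs and accept an optional
cutoff parameter.

## Distance census

Snapshots are exported multi-model PDBs (read with MDAnalysis) or plain
coordinate TSVs. Per frame, the loop reference atom and active-site
reference atom are resolved on both chains — defaults: the S220 hydroxyl
proton (HG) and the V197 Cγ1 methyl proton (HG11), with heavy-atom
fallbacks Oγ/Cγ1 for proton-free exports (logged, recorded in provenance;
the ~1 Å offset is small against the 15/25 Å thresholds). The four
distances per frame are classified intra (A→A, B→B) or inter (A→B, B→A).
Close approaches are counted in the half-open window [5, 15) Å with exact
rational arithmetic before float conversion; the intra-protomer floor of
25 Å corresponds to the nitroxide PRE observability ceiling. Coordinates
are used as-is: periodic-boundary reimaging belongs to the exporter, and
frames are equally weighted. Distances use an explicit component-wise sum
of squares so that an independent brute-force recomputation is bit-exact.

## Forward models (synthetic data)

The generators define the study conditions and give every stage a
recoverable ground truth.

* **PRE tables.** The label position is a weighted ensemble; probe rates
  are Γ₂ = K·Σᵢwᵢrᵢ⁻⁶ (fast-exchange ⟨r⁻⁶⟩ averaging — appropriate for a
  highly flexible loop; exchange-regime lineshape physics is out of scope).
  The Solomon–Bloembergen prefactor is lumped into one constant K,
  calibrated so that Γ₂(25 Å)·t = 0.05 with t = 10 ms: a probe at the
  25 Å ceiling shows ≈5% attenuation, indistinguishable from 1 at 3σ with
  the default 2% peak noise — reproducing the stated observability limit.
  Intensities are I_dia = I₀ + ε, I_para = I₀·exp(−Γ₂t)/c + ε with
  Gaussian ε (σ = 20 on I₀ = 1000), clipped at zero (clipping recorded in
  the truth table).
* **Solvent-PRE tables.** Per-residue signed charge ψ couples
  Boltzmann-like: Γ₂(∓) = Γ₂⁰·exp(±κψ), the simplest monotone model that
  preserves the sign logic the analysis tests. Explicit electrostatics
  (Poisson–Boltzmann) is a non-goal.
* **Snapshots.** 600 frames with two inter pairs per frame (1200 inter
  records). Each inter distance is independently close (uniform [5, 15) Å)
  with probability f (0.08 Trp-like, 0.005 Tyr-like) else far (uniform
  (25, 45) Å); intra distances are always far. The four planted distances
  are realized exactly as 3D coordinates (site atoms 30 Å apart, loop atoms
  placed by two-sphere intersection, a random rigid motion per frame), so
  the census must *measure* them. Triangle feasibility truncates an intra
  draw to [25, 30 + d] Å when its partner inter distance d is close; inter
  marginals — the quantity under test — are exact.

What the generators do **not** emulate: spectral overlap and assignment
gaps, rotamer-dependent label positions, correlated noise between peaks,
cosolute binding to pockets, and conformational kinetics (frames are
i.i.d., not a trajectory). Passing recovery tests therefore demonstrates
the correctness of the estimators and bookkeeping under the assumed noise
model, not robustness to those real-data pathologies.

## Numerical and design choices

* Tables are TSV/CSV with case-insensitive headers; floats are parsed
  round-trip-exact and written with 17 significant digits, so
  write-then-read is bit-exact and pipeline runs are byte-reproducible.
* Pairing is an outer join on (residue index, methyl id): the count
  identity |a| + |b| = 2·pairs + unmatched_a + unmatched_b is asserted in
  tests; nothing is dropped silently. Methyl stereo-labels are opaque
  strings.
* All generators take an explicit integer seed (`numpy.random.default_rng`)
  and are bit-deterministic.
* The workflow stage runner hashes parameters + input bytes; a stage whose
  hash matches the previous run log is skipped (re-entrancy), and every
  parameter used is echoed to the run log.
* Problem sizes in the tests and acceptance script (100 planted rates,
  10⁵ Monte-Carlo draws, 30-residue charge maps, 600-frame snapshot sets)
  are the package's chosen desk-scale study conditions: large enough that
  every tolerance is statistically meaningful, small enough to run in
  seconds.

## Known limitations

* Γ₂ is never converted to explicit distances for structure refinement;
  ratios and bounds are used semi-quantitatively.
* ϕ is a proxy with arbitrary units, not a potential in mV.
* Rate estimation supports exactly two time points; full decay-curve
  fitting (> 2 points) is out of scope.
* The distance census analyzes exported snapshots; it does not run or
  validate the simulations that produced them.
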