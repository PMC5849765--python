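# Methods

## Equilibrium model

A system is described by free *components* (Gd³⁺, Ca²⁺, Zn²⁺, H⁺, the five
synthetic chelators, six endogenous ligand classes) and *species*, each with
a cumulative formation constant β on the molar scale and an integer
stoichiometry ν over the components. Hydroxide-bearing species are encoded
with negative proton stoichiometry (log *β convention), so water enters only
through the table-level pKw (13.78 by default; it is metadata plus a
conversion aid — every hydrolysis species carries its own log *β).
Temperature and ionic strength are likewise metadata: constants are used as
published, with no Davies/SIT corrections, because the source constants were
themselves determined under near-physiological conditions and the protocols
compare chelators against each other under identical media.

Given totals *T*ⱼ and a fixed proton concentration 10^(−pH), the solver
finds free concentrations *x*ⱼ with

    T_j = x_j + Σ_i ν_ij c_i,      c_i = 10^(log β_i) Π_k x_k^(ν_ik)

to a relative mass-balance tolerance of 10⁻¹² (the "high precision"
setting), max 200 iterations. Numerics:

* Variables are ln *x*ⱼ, which keeps concentrations positive across the
  >12 decades spanned by the dilution scans.
* Newton steps use the analytic Jacobian and a damped line search (step
  halved up to 30 times until the residual 2-norm decreases).
* Cold starts (*x*ⱼ = *T*ⱼ/2) first run a half-power multiplicative
  mass-balance correction (*x* ← *x*·(T/T_calc)^½, the classical
  successive-approximation update, convergent for ν ≤ 2) until the largest
  relative residual is below 1; the same update serves as rescue step if a
  Newton step is rejected. Dilution scans warm-start each point from the
  previous solution (continuation).
* Exponents are capped (≈ e⁷⁰⁰) so intermediates stay finite; convergence
  failure is always reported explicitly (`converged=False`), never
  silently.
* A total of exactly 0 drops the component (and every species containing
  it) from the solve, which is how metal-free and chelator-free controls
  and the zero-competitor reduction are realized.

Determinism: identical problems yield bit-identical results (fixed
iteration schedule, no randomness).

## Constants table

The packaged table holds 74 formation equilibria: protonation ladders for
the five chelators and six endogenous ligand classes, the 1:1 Gd/Ca/Zn
complexes of the chelators (plus protonated MHL complexes for DTPA), and
the Gd/Ca/Zn complexes of hydroxide, carbonate, phosphate, citrate,
oxalate and lactate. Entries are critical-selection literature values
(Martell & Smith and NIST-style selections; Baes & Mesmer for hydrolysis),
flagged per entry in the provenance column. Two anchors deserve note:

* β(Gd–HOPO) = 20.60 is back-computed from the reported pH-7.4 conditional
  constant 20.5(1) together with the HOPO protonation ladder (highest
  pKa 6.6), so `conditional_stability_constant(Gd, HOPO, 7.4)` reproduces
  20.5 by construction of the table, not of the code.
* The highest pKa values of HOPO (6.6), DTPA (10.4) and DOTA (11.2) are the
  reported ones; the rest of each ladder is from the critical selections.

No Ca/Zn–HOPO complexes are tabulated (HOPO is designed to reject the
biological divalents and no constants are established), so transmetallation
scans on HOPO raise a missing-species error by design. Ternary
metal–chelator–ligand species are not included.

The conditional constant at fixed pH is log K' = log β(ML) − log α_L(H)
− log α_M(OH), with α_L(H) = 1 + Σ_n 10^(log β(HₙL) − n·pH) and the metal
hydroxide side coefficient computed analogously from the table's negative-
proton species.

## Dilution and transmetallation protocols

The co-dilution grid runs total Gd from 10⁻³ to 10⁻¹⁵ M at 10 points per
decade (121 solves per scan), with the chelator co-diluted 1:1 mol/mol and
the endogenous pool fixed at phosphate 1.1 mM, carbonate 25 mM (treated as
a closed total, not an open CO₂ system), oxalate 9.2 µM, lactate 1.5 mM,
citrate 160 µM, pH 7.4. The release threshold is the 50% crossing of the
bound-fraction curve, located by log-linear interpolation between the
bracketing grid points of the monotonized curve (ripple above 10⁻⁹ would
be a solver defect and is asserted against in tests). Rankings report
thresholds within 0.3 log units (≈ factor 2) as ties, because absolute
positions on the dilution axis depend on the endogenous ligands included,
while threshold *ratios* between chelators are insensitive to that common
offset. Transmetallation scans add a constant competitor pool (Ca²⁺
1.1 mM or Zn²⁺ 15 µM) and are otherwise identical; a zero competitor total
reduces bit-identically to the plain scan.

## Balance-study pipeline

%RD is a compartment's activity divided by the animal's total recovered
activity. Urine and feces are cage-level samples (one cage per group), so
they are apportioned equally among the cage's animals for per-animal %RD;
with that convention each animal's compartments sum to exactly 100, and
group retention plus cumulative excretion closes to 100 exactly (the
conservation identity tested at 10⁻⁹). Group-level inference on excreta
should use cage totals (n = number of cages), which the frames expose.

* **Dixon's Q** — r10 variant, two-sided (both extremes tested, larger Q
  compared against the two-tailed critical value; Rorabacher 1991 table,
  n = 3–10, 90/95/99%). At most one removal per call, which at these group
  sizes makes removal idempotent. A zero range yields Q = 0, no outlier.
* **ANOVA** — classical between/within decomposition; zero between-group
  variation returns F = 0, p = 1 by convention.
* **Dunnett** — own implementation: the distribution of max |T| over the
  one-factor correlated multivariate t (λᵢ = √(nᵢ/(nᵢ+n₀))) is evaluated
  by nested Gauss–Legendre/Gauss–Hermite quadrature (48 nodes each),
  vectorized over t. It agrees with an independent reference
  implementation to <5×10⁻³ and its family-wise error calibrates to
  0.05 ± 0.01 under a 10⁴-replicate null simulation (both tested).
* **Tukey** — studentized-range HSD via the standard library routine.

Significance conventions follow the study design: p < 0.001 as the primary
threshold, p < 0.01 reported separately.

## Synthetic study generator

The generator emulates the murine ¹⁵³Gd design: 8 groups (saline control;
HOPO at −24, −1, +1, +24, +48 h; DTPA at −1, +1 h) × 4 mice, injected
activity 0.925 kBq, animal mass 31.7 ± 2.1 g, 4 daily urine/feces
collections, radiochemical recovery uniform in [0.92, 0.99] of the
injected dose. Group mean tables are anchored to the reported study-level
values — control skeleton 41, liver 11, kidneys 0.62, brain 0.063, ART 4
%RD and day-1 excreta 34.4 %RD at 95:5 urine:feces with ≈3 %RD/day after
and the late shift toward feces; whole-body retention 1.04 (HOPO −1 h),
6.3 (HOPO −24 h), 9.4 (DTPA −1 h) %RD; livers 0.78 (DTPA −1 h), 6.3
(DTPA +1 h), 1.68 (HOPO +48 h); kidneys 0.06/0.08 (HOPO/DTPA −1 h).
Compartments and groups without a reported value were fixed once to match
the qualitative findings (only those three groups under 10 %RD retention;
HOPO's fecal burst the day after delayed treatment; DTPA urinary-only
excretion) and to make every group sum to exactly 100 %RD. The reported
"nearly 60%" control retention and the printed excretion schedule overlap
slightly when forced to the 100% budget; the printed compartment values
were kept and the slack absorbed into the unreported carcass-remainder and
day 2–4 excreta, giving 58.1 retained / 41.9 excreted.

Draws are truncated normals (clipped at zero) renormalized per animal to
100 %RD, then scaled to activities by the recovery draw. Renormalization
preserves the anchored means (law-of-large-numbers tested at n = 1000) but
attenuates the configured SD of the largest compartments (e.g. skeleton SD
4 → ≈2 %RD after renormalization) and couples compartments within an
animal; per-animal inter-organ correlations of real data are otherwise not
modelled, and there are no organ kinetics beyond the daily excreta
schedule. Passing tests therefore validate the *pipeline arithmetic and
inference*, not the reproducibility of the animal experiment.

The brain-outlier scenario plants the deterministic control-group quartet
{0.060, 0.063, 0.065, 0.095} %RD (renormalization then excludes the brain
cell so the values survive exactly): Dixon's Q for the suspect is
(0.095−0.065)/(0.095−0.060) = 0.857 > 0.829, and the retained trio gives
the corrected 0.063 ± 0.003 %RD. Exactness of the quartet through the %RD
stage additionally needs a degenerate recovery window, since the
equal-share excreta denominator otherwise wobbles each animal's %RD by
~0.1%; the tests use `recovery_range=(0.95, 0.95)` for that scenario.

`generate_random_thermo_system` draws ≤3-component/≤6-species systems
(log β ∈ [2, 25], ν ∈ {1, 2}, totals log-uniform in [10⁻⁹, 10⁻²] M) used
to verify the solver against a brute-force residual-minimizing grid search
(60–100 points per decade-spanning axis, twice refined) on 100 seeded
systems.

## Problem sizes

Test-suite and acceptance workloads are desk-scale by design: five 121-point
dilution scans plus three transmetallation scans (~10³ Newton solves, a few
seconds), a 10⁴-replicate Dunnett null calibration, 100 random solver
systems with grid-search cross-checks, and 32-animal synthetic studies.

## Known limitations

* Equilibrium only: kinetic inertness is outside the model, which is why
  macrocyclic DOTA ranks level with DTPA here yet outperforms it in vivo.
* No solid phases: GdPO₄ precipitation would deplete the dissolved pool
  and shift speciation at high phosphate; the model keeps all species
  soluble.
* Carbonate is a closed total; an open (fixed-CO₂) treatment would lower
  effective carbonate competition at high Gd.
* Release thresholds are comparative, not absolute: adding further
  endogenous challengers (proteins, other metals) would shift all curves
  by a similar offset.
* Dixon screening with all noise disabled flags the renormalization echo
  of the planted animal in every compartment — an artifact of the
  degenerate scenario, not of the screen.
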