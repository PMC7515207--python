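# Methods

## Model

The cell is a cylinder of half-length L with axial symmetry about
mid-cell; radial and angular variation is neglected (valid when
(Rc/L)² ≪ 1). After nondimensionalization — time in units of the dilution
rate μ, length in units of L, concentration per unit length in units of
μ/a₁ where a₁ is the reference association rate — the domain is x ∈ [0, 1]
with x = 0 mid-cell and x = 1 the pole.

**Chromosome density.** ρ̂(x) is the normalized local DNA-length density
with ∫₀¹ ρ̂ dx = 1/2 (each half-cell carries half the DNA). The default is
the experimentally motivated logistic profile
ρ̂(x) = 1/(1 + e^{20(x−1/2)}); a step profile (uniform on [0, 1−Δx], zero
in the DNA-free pole region of width Δx) and tabulated custom profiles are
also provided. Off-default logistic parameters and custom tables are
rescaled at construction to preserve the half-mass convention; custom
tables warn when the correction exceeds 1%. The printed normalization
condition for ρ̂ mixes dimensional and dimensionless forms; the convention
∫₀¹ ρ̂ = 1/2 adopted here is the reading consistent with the plotted
logistic profile, and the module enforces it uniformly.

**Available volume.** A species with radius of gyration r sees
v(x) = exp(−(r/r*)² ρ̂(x)), with (r*)² = Vp/(2κπLp) set by the DNA length
per volume. All radii are supplied as ratios r/r* (the worked examples in
the literature give only ratios); `geometry.r_star` converts absolute
radii when Vp, Lp, κ are known. A complex's profile is the product of its
parents' (independent hopping events), i.e. squared radius ratios add.

**Flux.** Diffusing species carry J = −(χ/ε) v² ∂x(y/v): Fickian
transport plus drift toward high available volume. ε = μL²/D is the
diffusion-to-dilution time-scale ratio (default 1e−3; diffusion is
milliseconds against minutes for dilution); χ is the species' diffusivity
relative to the reference species. Fixed species (DNA) have J ≡ 0.
Boundary conditions are zero flux at both ends (mid-cell symmetry, closed
pole).

**Reactions.** Binding pairs follow E + S ⇌(a, d) c →(κ) P + E + S, with
degradation of either partner active in complex form and dilution of all
species at rate 1. The lumped complex loss rate is
d̃ = γE + γS + d + κ + 1, and η = 1/d̃ measures binding speed (η ≪ 1 is
fast binding). Species flagged `conserved` (gene DNA, whose copy number is
maintained through growth) are neither produced, degraded nor diluted, and
every loss channel of their complexes returns them — this reproduces the
conservation D̄T = D̄ + c̄ exactly, matching the reduced transcription
model's stationary structure.

**Reduction.** For ε ≪ 1 (and, for fixed species, localization width
δ ≪ 1), the space-averaged dynamics equal the well-mixed ODE with each
association rate multiplied by a constant BCF θ*: ∫v̂_E v̂_S dx when both
partners diffuse, v̂ of the mobile partner at x* when one is fixed. The
discrepancy between PDE space averages and the reduced model is O(ε)
(plus O(δ) with fixed species); the test suite verifies the linear ε
scaling empirically and the 2% agreement of the transcription/translation
circuit at ε = 1e−3.

## Numerical choices

- **Quadrature**: composite Simpson on ≥2001 uniform points per smooth
  piece, split at density breakpoints so step profiles integrate exactly;
  a Richardson doubling step checks 1e−8 and warns otherwise. Endpoint
  samples are nudged ~1e−12 into each piece so one-sided limits are used
  at jump discontinuities (the step density itself returns the left value
  at its edge — a measure-zero choice irrelevant to integrals).
- **Spatial discretization**: cell-centered finite volume, default 200
  cells. Face fluxes use two-point differences of u = y/v with v at faces
  the geometric mean of adjacent cells: this conserves mass exactly
  (telescoping fluxes, zero column sums) and annihilates the equilibrium
  profile y ∝ v discretely. With v ≡ 1 the operator is the standard
  Neumann Laplacian.
- **Time integration**: BDF (`scipy.integrate.solve_ivp`) with a sparse
  Jacobian pattern, rtol 1e−8, atol 1e−10 — the ε⁻¹ flux and η⁻¹ binding
  terms make the system stiff. The reduced ODE uses the same integrator
  and tolerances so cross-model comparisons are clean. Solver undershoot
  is clipped to zero only in post-processing (warning above 1e−8).
- **Localized production / DNA**: a top-hat of half-width δ (default
  0.02) around x*, clipped to [0, 1] and renormalized so the space-average
  is exact regardless of δ; a truncated Gaussian (σ = δ/2) is available
  for smoothness studies. On the grid, profiles are discretized by cell
  averaging and rescaled so the discrete mass is exact.
- **Steady states**: long-time integration (probe horizon 200 time units)
  followed by Newton refinement to residual < 1e−10; persistent endpoint
  drift (relative > 1e−3 over the trailing quarter) signals the absence of
  a stable steady state, e.g. an oscillatory regime.
- **θ(t) from fields**: cell-width-weighted sums on the simulation grid,
  exact for the piecewise-constant finite-volume representation.

## Design decisions

- **Complex diffusivity in Case I** is not determined by the framework;
  the default is χc = min(χE, χS) — a complex diffuses no faster than its
  slowest parent — overridable per reaction.
- **Pointwise vs smeared fixed-species BCF**: θ* for Cases II/III
  evaluates v̂ at x* (the δ → 0 idealization); an optional window average
  over [x*−δ, x*+δ] is provided and converges to the pointwise value.
- **Clock QSSA identities**: eliminating the fast dimerization and
  DNA-binding variables folds the BCFs into the Hill constants,
  Kd,i ∝ 1/√θ. The product identities θA,1* = θ1*θ3* = v̂_Pa(x*ₐ)² (and
  analogously θR*, θA,2*) follow from the same algebra as the repressor's
  θ* = v̂² and are asserted as cross-checks between the composite and
  component BCF routes. The QSSA path is taken only when
  min(dᵢ)/max(γA, γR) ≥ 50; otherwise the full reduced model is
  integrated with a logged notice.
- **Hill constants in closed forms**: the steady-state mRNA/protein
  expressions use the exact lumped dissociation constants
  (d + κ + γ + 1)/a from the stationarity conditions, which reduce to the
  textbook K = d/a when unbinding dominates. This keeps the
  algebra-vs-integration consistency checks tight at 1e−6.

## Default parameter regimes

Rate constants for the preset circuits are not uniquely fixed by the
framework; the shipped defaults are pinned to the regimes the theory
assumes and version-controlled in the scenario fixtures:

- **TX/TL** (`TxTlParams`): binding fast relative to dilution
  (η ≈ 0.016), ε = 1e−3, RNAP pool nondimensionalized to 1, gene dose
  D̄T = 0.1, worked-example radii rs/r* = 0.3, rm/r* = 0.88,
  rR/r* = 0.44 (`PAPER_ESTIMATES`).
- **Polysome** (`PolysomeParams`): Nr = 10, βl = βt = 1e−3 and
  R̄/Kt = 1e−2, the fast-unbinding/low-saturation regime in which the
  closed-form protein expression is valid; the full mass-action reduced
  ODE agrees within 1%.
- **Repressor** (`RepressorParams`): lumped production/decay, K = 1,
  repressor pool P̄r = α/γr = 1 at steady state.
- **Clock** (`ClockParams`): chosen inside the relaxation-oscillator
  region of the Hill-reduced model at θ = 1 (activator decays 10× faster
  than the repressor, activation gain αA/γA·Kd1 ≫ 1), with elementary
  rates dᵢ = 50 giving clean QSSA separation. At these defaults the
  well-mixed model oscillates with period ≈ 64 time units, and enlarging
  the activator to ra/r* = 1 with both genes at the pole (θA ≈ 2.24,
  Kd1 and Kd3 shrink by ≈ 1.5×) moves the system out of the oscillatory
  region: oscillations quench in both the QSSA and full reduced models.

## What the synthetic scenarios do and do not show

All inputs are synthetic: scenario fixtures encode the study conditions
(radii ratios, localization, rate regimes) rather than measured rate
constants, so circuit-level results are qualitative orderings (pole vs
mid-cell transcription, repression strength vs repressor size, oscillation
quenching) plus the quantitative BCF values, which depend only on ρ̂ and
the radii. Passing tests demonstrate internal consistency of the PDE, the
reduction, and the closed forms under these conditions; they do not
calibrate absolute expression levels for a real strain. Known
limitations: 1-D axial geometry only (no radial structure, no moving
domain during division — time-varying ρ̂ can be supplied as a custom
density but no cell-cycle driver is included), deterministic mean-field
kinetics (no low-copy stochasticity), 1:1 binding stoichiometry plus the
polysome preset (no chains of complexes as reactants in the generic
network), and excluded-volume exclusion from chromosomal DNA only (no
plasmid-DNA exclusion).

## Problem sizes

The shipped configurations use a 200-cell grid, ε down to 1e−3,
horizons of 5–8 dilution times for the binding circuits and 600 time
units (≈ 9 periods) for clock oscillation calls; the convergence study
sweeps ε ∈ {1e−2, 5e−3, 2.5e−3}. These sizes resolve the boundary
layers and the O(ε) discrepancies being measured (halving ε halves the
PDE-vs-reduced gap well beyond measurement noise).
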