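# spatialcircuits

Deterministic ODE models of bacterial gene circuits assume a well-mixed
cell. Real bacteria are not well mixed: the chromosome forms a dense DNA
mesh around mid-cell that ejects large molecules (polysomes, ribosomes,
RNAP) toward the cell poles — the *excluded volume effect* — and a
circuit's DNA is often localized (chromosomal locus vs. pole-localized
plasmid). `spatialcircuits` is a toolkit for systems and synthetic
biologists who want to quantify what that spatial heterogeneity does to
their circuits without giving up ODE models.

## The model

The half-cell is the dimensionless axial interval x ∈ [0, 1] (x = 0
mid-cell, x = 1 pole), carrying a normalized chromosome density ρ̂(x) with
∫₀¹ ρ̂ dx = 1/2. A species with radius of gyration r sees the available
volume fraction

    v(x) = exp(−(r/r*)² ρ̂(x)),      (r*)² = Vp / (2 κ π Lp),

and, when freely diffusing, the flux

    J = −(χ/ε) v²(x) ∂/∂x [ y(t,x) / v(x) ],

which drives molecules both down concentration gradients and toward high
available volume. ε = μL²/D ≪ 1 (diffusion in milliseconds, dilution in
minutes) separates time scales. In that limit the space-averaged dynamics
of every binding reaction Eᵢ + S ⇌ cᵢ → Pᵢ + Eᵢ + S reduce to the
well-mixed ODE with one change: each association rate aᵢ is multiplied by
a constant **binding correction factor** (BCF)

    θᵢ* = ∫₀¹ v̂_E v̂_S dx   (both diffuse, Case I)
    θᵢ* = v̂_S(x*)           (enzyme fixed at x*, Case II)
    θᵢ* = v̂_E(x*)           (substrate fixed at x*, Case III)

where v̂ = v / ∫₀¹ v dx. θ* = 1 recovers the well-mixed model; θ* > 1
means spatial co-localization effectively strengthens binding. The package
provides the BCF calculators, a finite-volume PDE simulator to validate
the reduction, the reduced ODE integrator, and preset circuits
(transcription/translation, polysome loading, a dimerizing repressor, an
activator–repressor clock).

## Worked example

Translation of a 700-nt mRNA as a polysome: the mRNA (r/r* = 0.88)
simultaneously loads 9 ribosomes (each r/r* = 0.44) and a tenth ribosome
binds to release the finished peptide:

```python
from spatialcircuits import logistic_density, bcf_polysome, available_volume, bcf_fixed

rho = logistic_density()                       # nucleoid profile, steepness 20
loading, release = bcf_polysome(rm_rel=0.88, rR_rel=0.44, Nr=10, density=rho)
print(f"theta_l* = {loading.value:.2f}")       # theta_l* = 1.56
print(f"theta_t* = {release.value:.2f}")       # theta_t* = 1.07

rnap = available_volume(rho, 0.3)              # RNAP-sized species
print(f"pole gene: {bcf_fixed(rnap, 1.0).value:.3f}")   # pole gene: 1.045
print(f"mid-cell:  {bcf_fixed(rnap, 0.0).value:.3f}")   # mid-cell:  0.955
```

Reading: ribosome loading onto the polysome is 56% faster than a
well-mixed model predicts (both partners are squeezed into the DNA-free
poles), peptide release 7% faster — together up to a 67% higher protein
production at low ribosome saturation. Transcription is far less
affected: an RNAP-sized molecule binds a pole-localized gene ~4–5% more
effectively, and a mid-cell gene ~4–5% less, than well-mixed.

The same objects drive simulations, e.g. PDE vs. reduced-ODE comparison
for a full transcription/translation circuit:

```bash
spatialcircuits run --fixture fig5a --out out/
spatialcircuits clock --ra 1.0 --t-end 600     # large activator: oscillations quench
```

## Layout

- `geometry` — chromosome densities ρ̂, available-volume profiles v, r*
- `bcf` — θ* for Cases I–III, polysome variants, exact θ(t) from fields
- `network` — declarative circuit models, mobility cases, localized production
- `pde` — finite-volume reaction–diffusion integrator (excluded-volume flux)
- `reduced` — reduced space-averaged ODE model, steady states
- `circuits` — TX/TL, polysome, repressor, clock presets + closed forms
- `config`/`cli` — YAML scenarios, shipped fixtures, `spatialcircuits` CLI

See `docs/methods.md` for modeling assumptions, parameter choices and
numerical details.
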