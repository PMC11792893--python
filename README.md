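# amphistoma

Spatial statistics of stomatal patterning on amphistomatous leaves, and a
2-D porous-medium model of what abaxial–adaxial stomatal coordination is
worth photosynthetically.

## The problem

Amphistomatous leaves carry stomata on both epidermes, halving the CO₂
diffusion path through the mesophyll. If natural selection tuned stomatal
placement to minimize the distance from any chloroplast to the nearest
pore, three things should follow: stomata on each surface should be
*overdispersed* (more evenly spread than random), the two surfaces should
*coordinate* (a pore on one surface sitting over a gap on the other), and
larger stomata should serve larger patches of leaf. This package provides
the statistical and biophysical machinery to test all three on tables of
stomatal centroid coordinates, plus generators for the synthetic surfaces
those tests need as null models.

It is aimed at plant ecophysiologists and anyone doing point-pattern
analysis on bounded windows with Monte-Carlo nulls.

## What it computes

**Dispersion.** For a surface with `n` stomata in a window of area `A`,
the nearest-neighbour index is NNI = D̄_O / D̄_E with D̄_E = 0.5·√(A/n)
(the expectation under complete spatial randomness) and D̄_O the observed
mean nearest-neighbour distance. NNI ≈ 1 for random patterns and ≈ 2.149
for the densest-packing equilateral triangular lattice. The dispersion
index rescales it against two Monte-Carlo references matched to the same
window and count:

    DI = (NNI − median NNI_random) / (median NNI_ideal − median NNI_random)

so 0 means "random" and 1 means "ideal lattice". The ideal reference
integrates over density uncertainty: count ~ Poisson(λ), λ ~ Γ(n, 1),
conditioned on exactly `n` points landing in the window. Overdispersion is
tested one-tailed with an add-one Monte-Carlo p-value and
Benjamini–Hochberg adjustment across surfaces.

**Coordination.** Each surface is rasterized into a map of squared
distance from every pixel centre to the nearest stomatal centroid (NSD²).
Coordinated surfaces should anticorrelate pixel-wise; the test compares
the observed Pearson r against nulls with both surfaces redrawn uniformly
at random (matched counts), on the negative tail.

**Stomatal zones.** The Voronoi cell of each stomate, clipped exactly to
the imaging window, is its supply zone; the length–zone-area association
is estimated per (light, surface) group by OLS with a hierarchical
bootstrap (plants → leaves → refit) for the 95 % interval.

**Coordination advantage.** A finite-element solution of
∇·(D_eff ∇c) = a(c, y) on the symmetry-reduced leaf cross-section
[0, U/2] × [0, T_leaf], with D_eff = D_air·φ/τ, Farquhar-type volumetric
demand `a` (min of Rubisco- and RuBP-limited rates, Beer–Lambert light
profile), Dirichlet pores and no-flux walls. The advantage of offsetting
the abaxial pore to x = U/2 instead of aligning it at x = 0 is the log
response ratio ln(A_offset / A_aligned) of area-integrated assimilation.

## Worked example

```bash
python examples/01_dispersion_index.py
```

```
stomata:              75 in 0.386 mm^2
observed NNI:         1.448
random-null median:   1.050
ideal-grid median:    2.149
dispersion index:     0.362
overdispersion p:     0.0010
```

The surface (a minimum-spacing process in the standard 0.386 mm² window)
is significantly more evenly spaced than random (p = 1/1001, the smallest
value 1000 simulations can produce) but far from the triangular-lattice
ideal: DI = 0.36 on the 0–1 scale. The other scripts in `examples/` walk
through paired-surface coordination, Voronoi zones and slope recovery, the
FEM advantage, and the full pipeline; each prints a short interpretation
of its numbers.

```bash
python examples/04_coordination_advantage.py
```

```
typical leaf   A =   9.98 umol m^-2 s^-1   ln(A_off/A_al) = 1.93e-08  (~0.000 %)
thin + sparse  A =   4.99 umol m^-2 s^-1   ln(A_off/A_al) = 1.68e-03  (~0.168 %)
```

Even in the thin (101 μm), sparsely stomatous (U = 338 μm ≈ 10 mm⁻²)
leaf, where lateral diffusion is the main constraint, offsetting stomata
buys well under 1 %.

## Layout

- `src/amphistoma/leaf_data.py` — surface records, validation, CSV I/O
- `src/amphistoma/synthetic.py` — random / ideal-lattice / hard-core /
  paired generators and the synthetic study
- `src/amphistoma/spatial.py` — NNI, dispersion index, Monte-Carlo tests,
  BH adjustment, two-way ANOVA
- `src/amphistoma/coordination.py` — NSD rasters and the paired-surface test
- `src/amphistoma/zones.py` — clipped Voronoi zones and slope estimation
- `src/amphistoma/fem.py` — the porous-medium reaction–diffusion model
- `src/amphistoma/pipeline.py` — fixture study and end-to-end orchestration

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
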