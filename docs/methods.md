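# Methods

This note documents the models, numerical choices and defaults behind
`amphistoma`, and what the synthetic-data generators do and do not emulate.

## Dispersion of a single surface

The observed mean nearest-neighbour distance D̄_O uses no edge correction.
Boundary bias is instead cancelled by construction: every Monte-Carlo
reference (random or ideal) is simulated in the same window with the same
stomatal count, so the observed and null statistics carry the same bias.
Nearest neighbours are found with a k-d tree (`scipy.spatial.cKDTree`);
batch simulations use chunked dense pairwise distances, which is faster at
the n ≤ a-few-hundred scale of one imaging window. The test-suite oracle
is an explicit O(n²) loop.

The ideal reference is an equilateral triangular lattice. To propagate
uncertainty in the true density of a surface observed to hold n stomata,
each simulated lattice draws count ~ Poisson(λ) with λ ~ Γ(n, 1) (the
posterior of a Poisson rate under a flat prior), builds a lattice of that
density, applies a uniformly random translation over the lattice's
fundamental cell and a uniformly random rotation over [0°, 60°), and is
accepted only if exactly n points fall in the window. Rotation
randomization is not optional cosmetics: with translation alone the
in-window count of a lattice is quantized by its row/column structure, so
for most n the exact-count event has essentially zero probability and the
conditioning never accepts. With rotation the acceptance rate is a healthy
3–8 %; the rejection loop is vectorized over attempts and raises with the
measured acceptance rate if a budget of `max_rejections` attempts per
requested surface (default 10⁴) is exhausted.

Monte-Carlo p-values use the add-one rule p = (1 + #{null ≥ obs})/(1 + N),
which is never 0 and makes the test exact at level α whenever (N + 1)·α is
an integer. Both the p-value and the dispersion index reuse one simulation
set per surface. Family-wise control is Benjamini–Hochberg across all
single-surface tests (one family) via `statsmodels`; paired-surface tests
form a second family. Treatment/surface contrasts of density and DI use
two-way ANOVA with Type-II sums of squares, which keeps main-effect tests
well defined for unbalanced designs.

## Paired-surface coordination

Each surface is rasterized to the squared distance from pixel centres to
the nearest stomatal centroid (NSD²), default 64 × 64 pixels over the
0.6213 mm window (≈ 9.7 μm pixels; the field is smooth at interstomatal
scales and 64² is converged in pre-tests, with 32–256 available for
sensitivity). The statistic is the pixel-wise Pearson correlation of the
two rasters; squared distance is the default with plain distance as a
switch. The test is one-tailed toward *negative* correlation — the
direction coordination predicts — with the positive tail exposed as an
option.

A property worth knowing: under the null (independent uniform surfaces)
the NSD² correlation is *not* mean-zero. Pixels near the window edge are
stochastically far from stomata on both surfaces at once, inducing a
positive bias of about +0.04 to +0.07 across realistic densities. The
Monte-Carlo test remains exactly calibrated because its null distribution
carries the same bias, but raw correlations near +0.05 should not be read
as evidence of anti-coordination failure; the type-I error of the test is
verified at 5 % ± 2 % in the suite.

## Stomatal zones and the length association

Voronoi cells are computed after reflecting the point set across all four
window edges, which makes every cell of an interior point bounded and
terminates it exactly on the window boundary; a final intersection with
the window rectangle is numerical insurance. Boundary stomata keep their
clipped zones. The tiling identity Σ areas = window area holds to < 1e-9
relative and is asserted in the suite.

The length–zone-area association is estimated per (treatment, surface)
group by ordinary least squares, with a 95 % percentile interval from a
hierarchical bootstrap: plants resampled with replacement, then leaves
within each drawn plant, then the pooled stomata refitted. This replaces a
full Bayesian mixed-effects treatment deliberately: the estimand is the
marginal within-group slope, which the cluster bootstrap delivers without
a posterior sampler. The regression direction is configurable — zone area
on length is the reporting convention; length on zone area is the
direction in which a coefficient planted by the synthetic generator is
recovered without errors-in-variables attenuation, and is what the
parameter-recovery tests use.

## The porous-medium photosynthesis model

Geometry: by symmetry of a regular stomatal sequence with full
interstomatal distance U, the domain is [0, U/2] × [0, T_leaf], adaxial
surface at y = 0 (illuminated side), abaxial at y = T_leaf. The adaxial
pore is a Dirichlet segment of half-width 10 μm at the x = 0 symmetry
edge; the abaxial pore sits at x = 0 (aligned) or x = U/2 (offset). All
other boundaries are no-flux. No stomatal or boundary-layer resistance and
no substomatal cavity are modelled; both affect the two arrangements
nearly equally and largely cancel in the advantage ratio.

Transport: single homogeneous effective diffusivity D_eff = D_air·φ/τ
(defaults D_air = 1.57e-5 m² s⁻¹, τ = 1.57, φ swept 0.1–0.3); no
palisade/spongy split and no anisotropic tortuosity.

Demand: volumetric Farquhar-type kinetics,
a(c, y) = min(A_c, A_j) − Rd with A_c = Vcmax·(c − Γ*)/(c + Km) and
A_j = (J/4)·(c − Γ*)/(c + 2Γ*), J the smaller root of the
non-rectangular hyperbola θJ² − (αI + Jmax)J + αI·Jmax = 0 and
I(y) = I0·exp(−k_abs·y/T_leaf). These algebraic forms are total in c,
give a(Γ*) = −Rd exactly and −Rd in darkness. Defaults
(Vcmax 0.30, Jmax 0.60, Rd 0.003 mol m⁻³ s⁻¹; Km 0.029, Γ* 0.00175
mol m⁻³; α 6e-4 in volumetric units, θ 0.7, k_abs 1) are calibrated so a
201 μm leaf at I0 = 1000 μmol m⁻² s⁻¹ and a 400 ppm pore concentration
assimilates ≈ 10 μmol m⁻² s⁻¹; the advantage is a geometry-driven ratio
and is insensitive to the absolute kinetic scale. All constants are
dataclass fields and overridable.

Discretization: linear triangular elements on a structured grid whose cell
diagonals alternate with (i + j) parity, so the mesh has no preferred
lateral direction — this matters because the advantage is a tiny
left/right asymmetry signal. The reaction term uses a lumped mass matrix;
the nonlinear steady state comes from damped Picard iteration (damping
0.5, start c ≡ c_pore, relative-change tolerance 1e-8, max 200
iterations), reusing one LU factorization of the stiffness matrix across
iterations. The pore Dirichlet set is the boundary nodes inside the pore
segment; the resolution guard requires at least four mesh edges to
intersect the pore. Assimilation integrates the demand over the domain per
unit leaf-surface length; the boundary influx is recovered from the
Galerkin residual at the pore nodes, so the mass balance
|A_total − flux_in|/flux_in is a genuine convergence diagnostic (< 0.1 %
at the default tolerance). The linear-reaction limit is verified against
the 1-D cosh closed form to < 0.5 % at 64 × 64.

Mesh convergence of the advantage is checked on the thin-leaf/sparse-
stomata cell, where the signal (~1.7e-3) is far above the solver
tolerance; on thick, densely stomatous cells the advantage itself is
~1e-8 and a relative mesh-convergence test there would compare numerical
noise.

## Synthetic study and what passing tests show

The fixture study mirrors the design scale of the imaging campaign the
package targets: 66 leaves (two surfaces each) split over three light
treatments, two leaves per plant, in 0.386 mm² square windows. Abaxial
densities of 150/200/400 mm⁻² for low/medium/high light emulate the
observed plasticity direction; adaxial density is 0.8× abaxial, giving an
amphistomy ratio of ≈ 0.44. Overdispersion is produced by a hard-core
(minimum-distance) process with r_min = 0.4/√density, which lands the
dispersion index in the 0.15–0.35 band typical of real surfaces, and
guard-cell lengths are planted as 18 μm + 600 μm/mm² × zone area + 2 μm
Gaussian noise.

The generators deliberately do not emulate stomatal development (cell
lineages, one-cell-spacing rules), within-leaf density gradients,
measurement error in centroid placement, or any true abaxial–adaxial
coupling. Passing tests therefore demonstrate that the statistics are
calibrated and recover planted effects under their stated nulls and
alternatives — not that real leaves behave like the fixtures. Analyses of
real data additionally depend on imaging and segmentation quality, which
are out of scope.

## Problem sizes used in the checked results

The suite's study-scale checks use 200 fixtures per dispersion anchor with
10³ simulations each, 500 replicates per type-I calibration (199-or-99
simulation nulls, which keep the add-one test exact at α = 0.05), 100
seeds for slope-recovery coverage, and a 36-cell FEM sweep at 64 × 64 with
both arrangements per cell. The acceptance script sweeps the full
4 × 4 × 3 × 3 grid (144 cells, 288 solves).

## Known limitations

- The FEM is 2-D and homogeneous; real mesophyll is 3-D, spatially
  heterogeneous, and more tortuous laterally in the palisade, which could
  raise the coordination advantage somewhat.
- Exact-count lattice conditioning requires rotation randomization (see
  above); fixed-orientation lattices are available but cannot be
  conditioned on most counts.
- The coordination raster treats stomata as points; pore extent and
  substomatal cavities are ignored.
- Percentile bootstrap intervals with few plants (< 4) can undercover;
  the coverage guarantee is verified at 4 plants × 2 leaves.
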