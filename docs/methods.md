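# Methods

This note documents the models, numerical choices and limitations of
the package in one place. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Registration model

A deformation is stored extrinsically: one warped unit vector per
source-mesh vertex. A field is accepted as diffeomorphic when no face
of the warped mesh reverses orientation (the signed volume of the
origin–face tetrahedron keeps its sign on every face). This is an
operational surrogate for invertibility that is cheap, exact on the
mesh, and sufficient for every consumer in the package (label transfer,
inversion by scattered interpolation, area measures).

The demons iteration alternates:

1. **Similarity (Gauss–Newton).** At each moving vertex with current
   warped position y, the fixed features and their gradients are
   sampled at y; the 2×2 system
   (JᵀJ + β⁻²I) u = Jᵀ(F_M − F_F(y)) is solved in an orthonormal
   tangent basis at y. Fixed-feature gradients are precomputed per
   vertex by a least-squares fit of one-ring finite differences in the
   tangent plane and interpolated barycentrically.
2. **Smoothing.** The proposed update is averaged over the one-ring
   (`update_smoothing_passes`), applied, and the total displacement
   field is then averaged (`field_smoothing_passes`) — an approximate
   heat kernel of width ≈ √passes edge lengths standing in for the
   hidden-transformation smoothness penalty.

Per-iteration displacements are capped at `step_cap_factor` × mean edge
length; if the candidate folds the mesh or raises the SSD, the update is
halved (up to 10 times) before the level gives up. Sum-of-squares
mismatch is therefore non-increasing across outer iterations at every
level, and every returned field passes the fold check.

**Multi-scale schedule.** Levels are a smoothing pyramid on the native
mesh rather than a remeshing hierarchy: at level s (named by icosphere
subdivision number, default (3, 4, 5)), the feature maps are low-pass
filtered with 4^(finest−s) one-ring averaging passes. This keeps one
vertex set for the whole solve and works for meshes whose resolution is
not an icosphere level, at the cost of not shrinking the linear-algebra
size on coarse levels (immaterial at these mesh sizes).

**Engine defaults.** β = 1; functional-stage smoothing is light
(2 field passes, 1 update pass, 30 outer iterations, tolerance 1e−5)
so that warps at the scale of a parcellation region or functional cap
remain recoverable; the structural stage uses a heavily regularized
configuration (10 field passes, 2 update passes, 15 iterations,
tolerance 1e−4) because the structural maps are smooth and band-limited
and a conservative anatomical prior is wanted before functional
channels enter. With ~10 field-smoothing passes in the functional stage
the cap-scale twist of the simulation is not recoverable (the kernel
width exceeds the feature scale); this motivated the split.

**Point location** uses central (gnomonic) projection: the containing
face of a query direction is found among faces incident to the nearest
vertex and its one-ring (a cached padded table), with a brute-force
scan as fallback; barycentric coordinates come from a 3×3 solve.
Rotational fields are interpolated exactly by this scheme. **Inversion**
interpolates the original vertex positions over the warped triangulation
(valid because fold-free) and renormalizes; round-trip error is far
below the 5e−3 rad working tolerance, so no fixed-point refinement is
applied.

## Functional-network features

The vertex×region connectivity matrix holds Pearson correlations
between every vertex series and every region-mean series. Zero-variance
series (masked or constant vertices) produce zero entries and a counted
warning rather than an error — they are routine in masked data.

**Node degree** binarizes the whole N×R matrix at one global threshold,
the k-th largest entry with k = round(0.25·N·R) by default; a vertex's
degree is its surviving-entry count. The k-th-largest formulation makes
the retained count exact (an interpolated quantile can be off by one)
and is invariant to any strictly monotone transform of the
correlations.

**PCA convention.** Connectivity matrices are column-centered (each
region's column has zero mean over vertices) and decomposed by SVD;
spatial modes are the left singular vectors (unit norm), λᵢ the
eigenvalue proportions of total variance. Group PCA decomposes the
horizontal concatenation of all subjects' λ-weighted components the
same way. Dual regression is two least-squares stages: the centered
matrix is regressed onto the group spatial components to obtain region
profiles, then onto those profiles to obtain subject spatial maps,
which are renormalized; each component's λ is its share of the jointly
explained variance, apportioned by its rank-one term (components may
correlate, so naive per-component shares can overlap and exceed one).
Projected component order always follows the group set — correspondence
across subjects and species is the point; no reordering by variance.

**Sign conventions.** PCA signs are indeterminate. Cross-group pairing
records the correlation sign; group averaging harmonizes each subject's
component against the reference before averaging (ties resolve to the
positive orientation). Pairing is greedy on |r|, adequate and
deterministic at ten components per side.

## Channel blending

Each raw channel (structural maps, node degree, each component map) is
z-scored over non-medial-wall vertices, making units commensurate, then
multiplied by (1−wᵢ) for structural and wᵢ for functional channels,
wᵢ = i/(i+1). A plain z-score would erase the eigenvalue weighting of
the component channels, so the pipeline rescales PC channel i by
λᵢ/λ_max after z-scoring, using the fixed-side reference λ on both
sides; the leading component keeps full weight and weaker components
contribute proportionally, preserving the intended ordering without
reintroducing unit mismatch.

## The iterative loop

Stage one registers on structural channels only. Each functional
iteration i then: transfers the fixed parcellation through the current
field (nearest-vertex; label 0 propagates; empty regions are padded
with zero columns so the region dimension stays aligned with the fixed
side), recomputes the moving connectivity, degree and dual-regression
projected components (the fixed-side reference components are sampled
at the current warped positions before projecting), assembles the
blended features, and re-runs demons warm-started from the current
field. Fixed-side functional channels are computed once and frozen —
only the moving side updates, so the reference is stable.

**Step acceptance.** SSD values at different wᵢ are not directly
comparable, so the loop tracks the weighted SSD divided by the summed
squared channel weights. An iteration that does not lower this
normalized mismatch is rejected and ends the loop. This guard exists
because, once the genuinely recoverable warp has been absorbed
(typically after the first functional iteration in the simulation), the
growing functional weight lets further iterations fit the irreducible
mismatch floor between the two spheres' independently computed
functional channels — node degree is the noisiest (threshold
discreteness), the component maps much cleaner — which slowly degrades
the alignment. The cap of 5 iterations (4 in the simulation) bounds the
same risk from above.

## Synthetic data and the ground-truth experiment

The generator emulates only what the method consumes:

- **Structural maps**: random band-limited spherical-harmonic mixtures
  with distinct spectra (C: l ≤ 12, SD: l ≤ 8, MY: l ≤ 6), standardized.
  They model smooth cortical maps, not folding patterns.
- **Parcellation**: geodesic Voronoi regions from farthest-point-sampled
  seeds; R = 180 regions by default, all non-empty.
- **Time series**: six latent signals with smoothed region-driven
  spatial loadings plus white noise (σ = 1 against unit-variance
  loadings; at the defaults the planted structure carries >90% of the
  connectivity variance — asserted in the suite). No hemodynamics:
  only the correlation structure matters to the method.
- **Ground-truth deformation**: a structure-consistent warp composed
  with a functional-only warp. The structural part is itself a demons
  output — the structural fields are sampled through a small smooth
  random warp (max displacement 0.15 rad) and the originals registered
  to the jittered copy — so it is correlated with structural gradients
  by construction. The functional part is a twist: a rotation about the
  cap-center axis whose angle tapers smoothly to zero at the cap
  boundary (radius 0.7 rad, amplitude 0.8 rad), identity outside the
  cap; amplitudes auto-reduce if the fold check fails.

Inside the functional cap the structural maps are smoothly blended to
their cap mean, so the twist is invisible to structural channels; the
leading latent loading carries an off-center in-cap blob, so the
functional channels do see it. This is the mechanism the experiment is
designed to probe: structural registration leaves the in-cap error
several times the out-of-cap error, and only the functional iterations
remove it. All data (structural maps, time series, parcellation) are
resampled through the full composed warp to build the fixed sphere; the
reference field the registration should recover is its inverse.

Every stochastic component draws from a seed spawned deterministically
from the single config seed; identical configs give bit-identical trace
CSVs.

**What passing does and does not show.** The simulation demonstrates
that the iterative scheme recovers localized functional-only
deformations that structural matching cannot, under clean conditions:
shared noise between the two spheres (the fixed data are resampled from
the same acquisition), no inter-subject variability in the planted
modes, no medial wall, and spherical-harmonic "anatomy". It does not
certify performance on real multi-subject or cross-species data, where
the channel mismatch floor is larger and homology itself is the unknown.

## Problem sizes

The default experiment uses the subdivision-4 icosphere (2562 vertices,
5120 faces), 180 regions, 300 timepoints and 4 functional iterations;
the acceptance script repeats it for ten seeds. These sizes preserve
the structure of the protocol (vertex count ≫ region count ≫ component
count; several vertices per region) at desk scale.

## Known limitations

- The fold check certifies orientation preservation on mesh faces, not
  a continuous diffeomorphism between meshes of differing resolution.
- Greedy component pairing is not an optimal assignment; fine at
  N₂ = 10.
- The smoothing-pyramid multiscale does not reduce per-level problem
  size; very large meshes would want true coarsening.
- Medial-wall handling is by mask exclusion from z-scoring and
  statistics only; geometry always includes the wall.
- The degree channel's global threshold makes it sensitive to the
  overall correlation distribution; rank-based by construction, it is
  still the noisiest channel across recomputations.
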