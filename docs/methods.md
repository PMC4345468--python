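# Methods

This note documents the models, estimators and numerical choices behind
`nucleomap`, what the synthetic-data generator does and does not emulate,
and the problem sizes used in the validation experiments.

## Problem setting

The data are replicate confocal z-stacks of cell nuclei; one channel stains
the nuclear envelope, another a point-like nuclear compartment. The
question is whether the compartment has a spatial preference inside the
nucleus — is its distribution aggregated toward some region, or dispersed
away from one, relative to complete spatial randomness (CSR, a homogeneous
Poisson process inside the nuclear volume)? Because nuclei differ in shape
and orientation, evidence must be pooled across replicates in a
shape-respecting way: that is what the aggregate map construction does.

## Segmentation

The envelope channel is thresholded globally (Otsu on the full 3D
histogram by default; fixed-value and quantile thresholds are available —
the convex-hull step makes the boundary robust to the exact thresholder).
The boundary is the convex hull of the largest connected foreground
component's voxel centres in physical coordinates; fibroblast-like nuclei
are smooth and convex, so the hull is a faithful delineation. Compartments
are connected components of the thresholded compartment channel
(26-connectivity — standard for blob detection in anisotropic stacks;
configurable), filtered at a minimum size (default 4 voxels, rejecting
single-voxel noise), and reduced to the **unweighted** centroid of their
voxel centres: binary centroids are stable under threshold changes, and an
intensity-weighted option exists. Centroids that fall marginally outside
the hull are clipped onto its surface and flagged.

Voxel `(k, j, i)` maps to the physical point
`((i+0.5)sx, (j+0.5)sy, (k+0.5)sz)`; all downstream geometry is in
physical units because confocal stacks are strongly anisotropic.

## Ovoid tip and correspondence landmarks

Nuclei have no biological landmarks, so correspondence is constructed
geometrically. The **ovoid tip** — the most pointed end of the boundary in
2D projection — seeds the in-plane orientation; the stack (gravity) axis is
shared by all replicates, so only rotations about z are allowed and the
frame stays right-handed (reflections would flip a physical chirality).

Pointedness is measured as **cap-area pointedness**: project the hull
vertices to the xy-plane, take the principal axis of the 2D hull, and for
each end compute the fraction of the projected hull area inside a cap of
depth 20% of the major-axis length; pointedness is the reciprocal of that
fraction. An area measure was chosen over a perimeter measure
deliberately: area integrates over the cap, so small boundary
irregularities (bumps of a few percent of the radius) perturb it far less
than they perturb the perimeter — in validation on bumpy synthetic shapes a
perimeter measure mis-picked the end in roughly 30% of cases, the area
measure in none, with a maximum angular error near 3° against ground
truth. Exact ties (ideal symmetric bodies) are broken deterministically
(larger maximal cap-vertex distance from the 2D centroid, then
lexicographic vertex order). A per-replicate manual tip override is
accepted for nuclei without a clear tip.

Landmarks are ray-cast from the volume centroid of the oriented boundary:
polar angles `θ_j = jπ/(n_rings+1)` about the +x pole axis and azimuths
`φ_k = 2πk/n_per_ring` measured from +z. "Regularly spaced" is interpreted
as regular in the solid-angle parametrization, which gives exact
cross-replicate index correspondence on convex bodies. Defaults
`n_rings = 9`, `n_per_ring = 16` (L = 146); landmark count needs no fine
tuning for these simple shapes.

## Generalized Procrustes analysis

Each landmark configuration is centred and scaled to unit centroid size;
the algorithm then alternates (a) the closed-form optimal proper rotation
of each configuration onto the current mean, (b) the closed-form optimal
per-configuration scale, and (c) the constrained mean update — the
landmark-wise average renormalized to unit centroid size, which is the
exact minimizer of the summed squared distance under the unit-size
constraint. Every step is coordinate descent on the same objective, so the
objective is non-increasing (asserted in tests at every iteration).
Rotations are restricted to determinant +1. Convergence tolerance 1e-10 on
the mean update, default cap of 200 iterations (typical cohorts converge in
well under 10); a convergence flag is returned.

## Thin-plate-spline registration

Each replicate's landmarks are mapped exactly onto the mean landmarks by a
3D thin-plate spline with kernel φ(r) = r (the biharmonic fundamental
solution in 3D, constants absorbed into the weights; the 2D log-kernel
would be wrong here). The standard block system (kernel block, affine
block, orthogonality side-conditions) is solved densely; no smoothing is
applied because landmarks are placed in exact correspondence, though a
ridge term is available for ill-conditioned cohorts. The fitted transform
reproduces similarity maps with vanishing kernel weights and interpolates
landmarks to < 1e-8 relative residual (both asserted).

Compartment centres are pushed through the replicate's spline; the fused
set over replicates is the aggregate map. Points landing outside the mean
hull are **clipped** to the hull surface, not discarded (discarding would
bias boundary intensity), and the clip rate is reported as a QC metric.
Note a structural property of the clip rate: the mean hull is the convex
hull of L landmark points, a polytope inscribed in the smooth average
surface, and likewise each replicate's compartments live in its full
(finely faceted) hull. Compartment centres in the thin shell between a
replicate's smooth hull and its inscribed landmark polytope map just
outside the mean polytope, so the clip rate at L = 146 is typically 5–10%
— this is landmark discretization, not spline overshoot (points drawn
inside the source landmark polytope end up outside the mean polytope only
~0.2% of the time). Observed and null patterns are clipped identically, so
the Monte-Carlo calibration is unaffected.

## Intensity estimation

The mean shape is voxelized on an isotropic grid (default ~64-cube
bounding resolution; the validation experiments use 32- and 24-cube
equivalents) and the intensity — expected compartment centres per unit
volume per replicate — is estimated with a **Voronoi-cell estimator**:
every interior voxel is assigned to its nearest fused point (exact ties to
the lowest point index), and a point owning discretized cell volume `V_p`
contributes `1/(R·V_p)` throughout its cell. A point so crowded that its
cell contains no voxel centre deposits its whole mass `1/R` into its
nearest interior voxel. The estimate therefore integrates exactly to
`(Σ nᵢ)/R` at any resolution.

The estimator is bandwidth-free, matching the motivation of avoiding a
smoothing-parameter search. Two properties to keep in mind: (i) the
per-voxel values are scale-free — the Poisson–Voronoi cell-volume
distribution has constant shape, so the pointwise spatial CV does *not*
shrink as points accumulate; consistency holds for regional averages,
which converge to the true level (verified on octants). (ii) An optional
natural-neighbour smoothing pass (inverse-distance-weighted average over
the owning point's Delaunay neighbours, mass-renormalized) reduces the
spatial CV about 2×; it is off by default and the inference path does not
use it.

## CSR inference

For each direction the rectified excess `(λ − λ₀)₊` or `(λ₀ − λ)₊` is
computed against `λ₀ = (Σnᵢ/R)/volume`. Cluster enhancement turns the
excess into a per-voxel statistic; three modes exist:

- **cluster_mass** (default): every voxel of a connected excess component
  receives the component's integrated excess (volume × mean height). This
  was chosen as the default after direct measurement: with the bare
  component *volume* as statistic, supra-λ₀ Voronoi cells under CSR
  percolate into components spanning 30–50% of the nucleus, so spatially
  compact true signals (central or annular aggregation) essentially never
  exceed the null maxima — the volume statistic has near-zero power.
  Weighting extent by excess height restores power while remaining a
  "size of connected regions of high or low intensity" measure.
- **cluster_size**: the bare component volume (useful for display, and the
  quantity shown in cluster-size visualizations).
- **tfce**: the threshold-free cluster enhancement integral
  `Σ_h e(h,v)^E h^H dh` (defaults E = 0.5, H = 2), integrating component
  extent across excess thresholds.

Component connectivity defaults to 6 (face-connected; conservative in 3D).

The null distribution is simulated, not assumed: for each of M iterations
(default 499; the validation experiments use 199) CSR patterns with the
observed per-replicate counts are drawn uniformly in each replicate's
*original* boundary and pushed through the replicate's *already-fitted*
spline — so the null maps suffer exactly the same nonlinear deformations
and clipping as the observed map, neutralizing deformation artefacts.
Transforms are cached, never refitted. Per replicate, one deterministic
child stream (derived from the master seed and the replicate index) is
chopped into per-iteration chunks, so iterations are independent and the
whole simulation is reproducible bit-for-bit.

Calibration uses the null distribution of the **maximum** statistic: voxel
v rejects at level α iff `(1 + #{null max ≥ statistic(v)}) / (M+1) ≤ α`.
This is a single test over the entire image with family-wise error control,
and Monte-Carlo p-values are never exactly zero. Because observed and null
aggregate maps are exchangeable under CSR, the any-rejection rate is
calibrated at α by construction; the validation run measures it at 0.05
for both directions over CSR cohorts. Per-voxel uncorrected p-values are
also returned but should be treated as exploratory.

Power near the boundary is structurally reduced: boundary voxels lie in
large Voronoi cells whose statistics are diluted, so true effects close to
the envelope may fail to reject — visible in the shell-exclusion
experiments, where the detected dispersed region starts slightly inside
the true exclusion zone.

## Synthetic data

The generator emulates cohorts of flat-lying fibroblast-like nuclei:

- **Shape**: an ellipsoid with semi-axes a ≥ b ≥ c (defaults drawn per
  nucleus from a ∈ [8, 10.5], b ∈ [5.5, 7.5], c ∈ [2.5, 3.2], in the same
  length unit as the voxel spacing — micrometres for the defaults), a
  smooth random radial bump field applied on the unit sphere *before* the
  axis scaling (affine maps preserve convexity, so bumps up to the allowed
  15% of radius cannot break convexity even for flat nuclei; convexity is
  still asserted post hoc), and a tip-sharpening stretch of the +x half
  (default ~0.25) creating a unique ovoid tip with a tangent-continuous,
  convex join. A random rotation about z and an in-plane translation are
  applied last (nuclei lie flat; the stack axis is common to all).
- **Patterns** (all in the shape-normalized fractional-radius coordinate,
  0 at the centroid, 1 at the boundary): `csr` (uniform by rejection);
  `central` — uniform draws radially shrunk by |N(0, σ_r)| with σ_r = 0.3;
  `annular` — fractional radius ~ N(r0 = 0.65, w = 0.1) on uniform
  directions; `shell_excluded` — CSR restricted to fractional radius
  ≤ 1 − t with t = 0.25 (an exclusion zone of the outer quarter of the
  radius, plausible for boundary-excluded compartments). These strengths
  are fixed defaults, chosen once as biologically plausible effect sizes.
- **Rendering**: two 8-bit channels — an envelope shell of default
  thickness 0.45 lying just *inside* the hull so that the shell's outer
  edge coincides with the ground-truth boundary (the lamina lines the
  inner nuclear membrane; a membrane-centred shell would bias the
  segmented hull outward by half the shell thickness), and spherical
  compartment blobs (radius 0.4) — Gaussian-blurred (σ = 0.15) and
  corrupted with Poisson shot noise (full-scale SNR 1/0.05 = 20 by
  default). Default stack geometry: 20 slices of 192×192 pixels at
  (0.36, 0.15, 0.15) spacing.

What the generator does **not** emulate: chromatin texture, nucleoli,
non-convex or mitotic nuclei, depth-dependent attenuation, chromatic
shift, or compartment size/intensity heterogeneity. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
geometry and statistics on idealized convex nuclei, not robustness to
every real-microscopy artefact; on real data the convex-hull and global
threshold steps are the components most exposed to those differences.

## Validation experiment sizes

- Type-I error: 200 CSR cohorts (R = 20 nuclei, Poisson(8) compartments
  per nucleus), M = 199 nulls, α = 0.05, 32-cube-equivalent grid; the
  any-rejection rate per direction must stay within two binomial standard
  errors of α (≤ 0.081).
- Power: 50 cohorts per alternative (R = 50, 10 compartments per nucleus,
  M = 199, 24-cube grid). Central: volume-weighted centroid of aggregated
  rejections within 0.15 mean hull radii of the centre. Shell-excluded: at
  least 90% of the dispersed rejection volume at fractional radius > 0.6 —
  a component-level test rejects whole connected components, whose ragged
  inner fringe always dips below any sharp radius at a few voxels, so
  confinement is asserted for the bulk of the rejection volume rather than
  its minimum. Annular: median fractional radius of aggregated rejections
  in (0.4, 0.9). Each must hold in ≥ 90% of cohorts.
- Accuracy: TPS interpolation < 1e-8 relative; similarity reproduction
  with kernel weights < 1e-8; GPA exact recovery < 1e-8 Procrustes
  distance; intensity mass error ≤ 1%; tip error < 15° over 100 random
  rotations; segmentation on noise-free renders — exact counts, centroid
  error under one voxel diagonal, hull volume within 5% (measured ~3%
  inward, the voxel-centre discretization bias).
- Determinism: bit-identical outputs across reruns at a fixed master seed.

`scripts/acceptance.py` recomputes scaled-down versions of these
experiments (60 CSR cohorts; 15 cohorts per alternative) plus the accuracy
and determinism checks, and writes all values as JSON.

## Numerical choices and degenerate inputs

- Convex hulls, Delaunay point location and KD-trees come from Qhull/SciPy;
  containment tests run through an early-exit half-space kernel (numba,
  with a pure-numpy fallback).
- Hull construction requires ≥ 4 non-coplanar points; GPA requires ≥ 2
  configurations spanning 3D; TPS requires ≥ 5 non-coplanar landmarks —
  violations raise typed errors naming the replicate.
- Ray-casting from the centroid requires the centroid to be interior
  (guaranteed for convex hulls).
- An all-zero image channel yields an empty mask with a warning, not an
  error; an empty compartment pattern is legal everywhere downstream
  (zero-count replicates still count toward R — they carry the information
  that the expected count is low).
- Voxel grids must target ≥ 100 interior voxels; Monte-Carlo testing
  requires M ≥ ceil(1/α) − 1 so the smallest attainable p-value can clear α.
- Exact nearest-point ties in voxel ownership go to the lowest point
  index; near-ties (within 1e-9 of the nearest distance) are recomputed
  exactly.
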