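# Methods

This note documents the models and numerical procedures behind
`spinemorph`, the assumptions they make, the parameters that matter and
what the synthetic test populations do and do not establish about real
microscopy data.

## Geometry carrier and units

All surfaces are indexed triangle meshes (`trimesh.Trimesh`) with
coordinates in micrometers. A spine is *watertight* when every edge
borders exactly two faces; watertightness is required wherever enclosed
volume is computed (divergence theorem via the signed tetrahedron sum).
The insertion point — the marked position where the spine emerges from
its dendritic shaft — travels in a sidecar CSV (`spine_id,x,y,z`)
because no standard mesh format carries per-object landmarks.

## Repair

Two acquisition artefacts are repaired in a voxel domain.

**Voxelization.** A voxel is occupied iff its centre lies inside the
surface, decided by z-column ray-crossing parity on a grid jittered off
lattice degeneracies. Centre sampling matters: marking every voxel the
surface *touches* dilates the shape by about half a voxel per side,
which for a 0.1 μm spine neck at the default 0.075 μm spacing doubles
its cross-section. With centre sampling plus the marching-cubes 0.5
iso-level the pipeline is volume-unbiased; a sphere of radius 10 voxels
round-trips within 0.5%, a 2-voxel-radius cylinder within 4%.
Structures thinner than ~1.5 voxels are at the resolution limit and
lose volume; the default spacing of 0.075 μm (matching common confocal
in-plane sampling, isotropic here for simplicity) resolves typical
spine necks but under-represents the thinnest ones.

**Fragmentation** (several closed components) is repaired by
morphological closing with an exact Euclidean sphere, implemented as
two distance transforms so cost is radius-independent. A schedule of
radii (3, 5, 8, 12, 18 voxels) is tried and the smallest element that
yields one component wins, so well-separated fragments are bridged
while intact geometry is distorted as little as possible. The default
ceiling of 18 voxels (reach 2 × 18 × 0.075 = 2.7 μm nominal) comes from
the waist condition for bridging: a gap g between end caps of radius c
closes only when √((r·s + c)² − (g/2)²) ≥ r·s, which for 1 μm gaps
between ~0.1 μm neck stumps needs r ≈ 16–18 voxels. Closing cannot
restore the material deleted inside a gap; the bridge is thinner than
the original neck.

**Detachment** (mesh ends above the insertion point) is repaired by
slice growth: the spine is rotated so the segment from its closest
vertex to the insertion point runs along −z, voxelized, and each empty
slice between the base and the insertion slice becomes a 2D Gaussian
blur (σ = 1.0 voxel) of the slice above, thresholded at 0.35. These
two values are chosen jointly so the iteration has a stable fixed point
at realistic neck calibers: at σ = 1 the blurred centre of a disk of
radius a is ≈ 1 − exp(−a²/2), so a 0.35 threshold sustains columns down
to ~1 voxel radius, whereas a 0.5 threshold extinguishes anything
thinner than ~1.8 voxels immediately. A `max_gap` guard (150 slices)
rejects spines marked absurdly far from the dendrite.

**Smoothing** is umbrella-operator curvature flow (each vertex moves a
fraction `step` = 0.1 toward its neighbour centroid, 10 iterations) —
enough to remove voxel staircases while changing enclosed volume by
well under 10%.

**Quality gate.** A repair is accepted when the repaired/original
volume ratio lies in [1/2, 2] and at most one component remains. The
band is deliberately wide on the low side: a fragment gap of up to 1 μm
genuinely removes neck volume (up to ~35% on thin spines) that no
closing can reinvent, and such repairs are still anatomically usable.

## Geodesic field

The descriptor is driven by the geodesic distance μ from the insertion
point. The default solver is the heat method: diffuse a point source
for a short time t over the cotangent Laplacian, normalise the gradient
of the diffused field, and recover μ as the potential whose gradient
best matches that unit field (two sparse factorizations). Two
numerical details:

* t is normally the squared mean edge length, but it is inflated so
  that the geodesic diameter spans at most 28 e-foldings of the heat
  kernel — beyond that the far field falls under the direct solver's
  rounding floor (~10⁻¹⁹ relative) and its gradient direction is noise.
  The diameter estimate comes from a Dijkstra pass on the edge graph.
* The raw heat solution is post-processed by a label-initialised
  Dijkstra relaxation, producing the largest function below it that is
  1-Lipschitz along every edge. This enforces the defining property of
  a distance field exactly, costs O(E log V), and only ever lowers
  values where the smooth solve locally overshot.

Accuracy on closed forms: pole-to-pole on a subdivided icosphere 3.117
vs π (−0.8%); flat-disk radii within 2%; the edge-graph Dijkstra
solver remains available as an upper-bound oracle.

## The 54-feature descriptor

The field μ is split into K = 7 intervals of equal width α/7
(α = max μ); region 1 is closed at 0, the rest are half-open, so μ = 0
maps to region 1 and μ = α to region 7. Each of the six interior
boundaries is a level-set polyline extracted by linear interpolation
along edges crossing the level (the largest-area loop is kept when a
level crosses several, as can happen on bumpy spines). Each loop is
fitted by an ellipse: the plane is spanned by the two leading principal
directions of the loop points; in-plane fitting uses the direct
least-squares conic (scikit-image's `EllipseModel`), with a
second-moment fallback for near-degenerate loops. Adjacent regions
share their boundary ellipse exactly — six ellipse objects bound seven
regions — which is what makes the skeleton well defined.

The skeleton is the chain c₀ (insertion), c₁…c₆ (ellipse centroids),
c₇ (apex = the vertex of maximal μ, ties to the lowest index). Features
in canonical order: 7 link heights |hᵢ|; 6 + 6 semi-axes R ≥ r;
6 bend cosines hᵢ·hᵢ₊₁/(|hᵢ||hᵢ₊₁|); 6 link colatitudes θ₂…θ₇;
6 + 6 ellipse-normal colatitudes/azimuths; 3 area ratios for the
ellipse pairs (2,4), (2,6), (4,6); 7 region volumes (convex hull of
consecutive boundaries, 64 points per ellipse, so the end regions are
cones over the base and apex); and the total mesh volume. That is
36 morphological + 18 directional = 54 features.

All angles live in a spine-local frame — origin c₀, +z along h₁, +x
along the first ellipse's major axis projected ⊥ z — making the whole
descriptor invariant to rigid motion of the input (verified to 10⁻⁵).
Two conventions keep it deterministic: ellipse normals are oriented
distally (positive dot with their link), and the major-axis sign is
fixed against the loop's first point, an intrinsic, rotation-covariant
reference. θ₁ is identically zero in this frame and is therefore not
stored; the first bend cosine and θ₂ describe the same angle, a
redundancy the simulator resolves in favour of the colatitude.
For spines with circular cross-sections the major-axis direction — and
with it the azimuth features — is numerically arbitrary; the
morphological features are unaffected.

The sum of region volumes underestimates the mesh volume by the bulge
outside the convex hulls (about 10–20% on round-headed shapes); both
are reported, V from the mesh as the feature, ΣVᵢ as a diagnostic.

## Model-based clustering

`SpineGaussianMixture` is a scikit-learn estimator wrapping EM
(`sklearn.mixture.GaussianMixture`; k-means++ starts, `n_init` = 10,
tolerance 10⁻⁶, ≤ 500 iterations, ridge 10⁻⁶ on covariance diagonals)
for every component count in [c_min, c_max], keeping the model with
the highest BIC = 2 log L − k log n. Columns are z-scored by default
(the 54 features mix μm, μm³, radians and dimensionless ratios); the
transform is stored in the model so samples map back to feature units.

Covariance structure is a real statistical decision in 54 dimensions:
a full covariance costs d(d+3)/2 + 1 = 1,540 parameters per component,
i.e. ~11,000 BIC points at n = 1,500, so with hundreds (not thousands)
of spines per cluster BIC will always prefer fewer full-covariance
components no matter how separated the clusters are. The estimator
therefore exposes `covariance_type` ("full" default, plus "diag",
"tied", "spherical"), and the recovery experiments use "diag", which
matches the diagonal-dominant populations they are run on. On such
populations (3 clusters, 500 points each, means 5 pooled standard
deviations apart) BIC selects C = 3 in 20/20 seeded runs and recovers
component means within ~2%.

Interpretation tools implement their textbook forms: |log₁₀ det Σ_c|
via `slogdet`; the Bhattacharyya distance
D = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ ln(det Σ̄ / √(det Σₐ det Σ_b)) with
Σ̄ = (Σₐ+Σ_b)/2; classical (Torgerson) MDS by double-centring −½D² and
clamping negative eigenvalues; the overlap ω_{j|i} by Monte Carlo from
component i with strict density-dominance counting (ties have measure
zero for non-degenerate Gaussians); Pearson χ² on contingency tables
without continuity correction, with a cluster-vs-rest collapsed mode
and a warning when expected counts fall below 5.

## Simulation

A simulated spine starts as a draw from one mixture component. Draws
are renormalised onto the descriptor's manifold before validity
checking: azimuths wrap, bend cosines and colatitudes fold back at
their boundaries (the folded-normal treatment of a bounded quantity
whose mean sits near the boundary — a draw "straighter than straight"
is the same geometry), and an axis pair sampled with minor > major
swaps. Rows that still violate invariants (negative lengths or
volumes) are rejected and redrawn; a rejection rate above 50% aborts
with a diagnosis. Folding biases the mean of a boundary-hugging angle
by at most about one standard deviation; interior features are
unbiased.

`build_skeleton` inverts the descriptor: the base sits at the origin,
h₁ along +z; each later link direction must make the stored bend angle
with its predecessor and the stored colatitude with +z, which
intersects two cones. Of the generically two solutions the one better
aligned with the stored ellipse normal is taken; when noise makes the
cones miss each other, the nearest achievable direction is used
provided the realised bend cosine is within 0.05 of the requested one
(beyond that the angle pair is genuinely contradictory and an error
names the link). Ellipse normals come directly from their stored
angles; in-plane major axes propagate by minimal twist.

`surface_skeleton` samples every ellipse at the same number of
parameter-uniform points (default 32), aligns consecutive rings by the
cyclic offset minimising total edge length, and joins them with
triangle strips. Between ellipses, intermediate rings (default 5 per
band) follow a shape-preserving cubic (PCHIP) through the six ellipse
rings, so the surface bulges smoothly through wide heads instead of
cutting straight frustum chords — monotone interpolation avoids
overshoot at sharp neck-to-head transitions. The end caps are domes
with a circular profile (ring scale √(1−t²) toward the pole): spine
ends are rounded, and both a straight cone and a single pole fan
systematically undercut head volume — a lone pole vertex of valence 32
is additionally dragged toward the first ellipse by subdivision.
With intermediate rings off, each band is exactly 2N triangles and
each cap an N-triangle fan. Meshes are closed, single-component and
genus 0 by construction (V − E + F = 2 is asserted in the tests).

Loop subdivision is implemented directly (faces quadrisect; edge
vertices take the 3/8–1/8 stencil; original vertices relax with
Warren's β = 3/(8k), 3/16 at valence 3) and cross-checked against an
independent implementation, which differs only at irregular vertices
where the two standard β conventions diverge.

**Realism score.** Real and simulated feature matrices (class-balanced)
are stacked and a pruned decision tree (`min_samples_leaf` = 5,
`min_impurity_decrease` = 0.01) is scored by stratified 10-fold
cross-validation. The pruning is essential to the score's meaning:
an unpruned tree can "detect" simulated rows by memorising near-exact
duplicates, reporting high accuracy even for statistically identical
populations. Calibration: two independent samples of one Gaussian
population score 0.5 ± 0.1; shifting one feature by ten standard
deviations scores ≈ 1.

## Synthetic study populations

The fixture factory builds solids of revolution — a cylindrical neck
with a gently domed base disk (sagitta 25% of the base radius; a
perfectly flat base would make the first geodesic band coplanar with
the insertion point, a degenerate zero-volume region) joined
tangentially to a spherical head, optionally bent along an arc whose
bending plane can precess (a helical axis) and with elliptical
cross-sections whose aspect tapers to circular above the head equator.
The taper matters: on an elongated head the geodesically farthest
vertex sits off-axis at the end of the major meridian, an unstable
apex that no reconstruction can reproduce. Default dimensions sit in
the biological regime of cortical spines (extents 0.5–4 μm, volumes
≲ 0.8 μm³): stubby (neck 0.35 × 0.28 μm, head 0.38 μm), thin
(1.4 × 0.10, head 0.22), mushroom-like (0.8 × 0.15, head 0.42), plus a
straight tube whose constant cross-section is the oracle for the
banding and ellipse fits.

Corruption operators emulate the two repair targets: `fragment`
deletes a band of faces of chosen geodesic width around mid-height and
recloses both sides (two watertight components, a real material gap);
`detach` removes the proximal part up to a chosen geodesic height and
moves the insertion point that far below the new base.

`sample_feature_population` draws labelled 54-feature populations from
a known mixture: a realistic hand-set base descriptor, cluster means at
simplex corners separated by `separation` × the pooled (RMS diagonal)
standard deviation, mild low-rank correlations (scale 0.1) on top of
diagonal covariances, and vectorised rejection to keep every row a
valid descriptor. `profile_feature_model` instead centres each
component on the descriptor *measured* from one bent, elliptic-section
profile mesh with small per-block spreads (3% relative on lengths and
volumes; 0.004–0.02 absolute on angle blocks, inside the margins the
bent templates keep from the validity boundaries) — geometrical
consistency is what lets these samples survive the full
simulate→extract round trip.

## What the synthetic results do and do not show

Passing tests establish internal consistency — the descriptor measures
known geometry correctly, the simulator inverts the descriptor, EM/BIC
recovers populations of the kind the generator produces, and the
repairs heal the damage the corruptors inflict — at desk-scale problem
sizes: 60 round-trip spines, 20 × 1,500-point mixture runs, 50
corrupted fixtures (sizes chosen to keep the full suite in a few
minutes on one core). They do not establish behaviour on real confocal
reconstructions, whose noise is not radial bumpiness, whose cluster
structure is unknown rather than planted, and whose fragment gaps need
not be clean bands. The round-trip tolerances are medians per error
family (heights and semi-axes ≤ 10% relative, bend cosines ≤ 0.05,
volume ≤ 15%): individual features at the ends of the chain — the
first and last heights, whose denominators are a few hundred
nanometres and whose termini (base pole, geodesic apex) are the least
stable landmarks — show larger relative errors.

## Known limitations

* The descriptor does not store the ellipses' in-plane major-axis
  azimuth; reconstruction propagates it by minimal twist, so strongly
  twisted spines are smoothed.
* The apex is the geodesically farthest vertex; on near-isotropic or
  multi-lobed heads it can jump between candidates, perturbing the
  last height and bend cosine.
* Voxel-domain repair is resolution-limited: necks thinner than ~1.5
  voxels lose cross-section; choose `voxel_spacing` accordingly.
* Full-covariance BIC selection needs thousands of spines per cluster
  in 54 dimensions; use `covariance_type="diag"` (or "tied") for
  smaller studies, as the recovery experiments do.
* Level-set boundaries at exactly coincident vertex values are nudged
  by 10⁻⁹α; pathological meshes with large perfectly-flat μ plateaus
  could still produce ambiguous loops.
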