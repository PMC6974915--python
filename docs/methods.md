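# Methods

This note documents the models, numerical choices and design decisions behind
`corollamorph`, and what the synthetic-data tests do and do not establish
about real data.

## Landmark template

The default template has 415 landmarks on a five-petal corolla: 25 primary
landmarks (5 each of roles I–V: lobe intersections, proximal/distal midrib
points, lobe-tube-rim × midrib intersections, proximal tube-tube-rim points)
and 390 secondary landmarks equally distributed along curves — per petal 15
on the lobe contour, 7 on the lobe midrib, 25 on the tube midrib; per
petal-pair rim 7 on the lobe-lobe rim and 25 on the tube-tube rim.  Naive
per-curve counts give 395 secondary points; the packaged convention treats
the distal entry of each lobe-lobe rim as the primary-I lobe-intersection
landmark (the two coincide anatomically), which removes 5 duplicates and
yields exactly 25 + 390 = 415.  The template is expanded from a JSON schema
shipped with the package, so deposits that used a different convention can be
described by a user-supplied schema rather than code changes.

Coordinates are stored in millimetres.  A voxel→mm conversion (36.547 µm per
voxel, the source µCT resolution) is available on read for files digitized in
scanner units.

## Procrustes alignment

Full GPA (shape): every configuration is centred, scaled to unit centroid
size, and iteratively rotated onto the consensus; the consensus is the
aligned mean, re-normalized to unit size each iteration (the standard scale
gauge).  Partial GPA (form) is the identical iteration without any scaling,
so centroid sizes are preserved in the aligned coordinates.  Rotations come
from the SVD of the cross-covariance with the smallest singular direction
sign-corrected, so reflections are never applied — corollas are bilaterally
organized and chiral, and a reflection would swap dorsal and ventral.
Convergence: RMS change of the consensus < 1e-8 or 100 iterations (both
configurable).  Alternating rotation and consensus updates each minimize the
summed squared distance to the consensus, so the objective is monotonically
non-increasing (asserted in tests).  No tangent-space projection is applied
before PCA; for the small shape distances typical of congeneric corollas the
difference is negligible, and PCA operates on aligned coordinates directly.

## Morphospaces

PCA uses the covariance of the flattened aligned coordinates (divisor S−1),
computed by SVD of the centred data matrix; at most min(S−1, 3K) components
are retained.  Coordinates share units, so no per-coordinate standardization
is applied (correlation-matrix PCA would distort shape space).  Axis signs
are fixed by making the largest-magnitude loading of each axis positive,
which makes scores and virtual flowers reproducible across platforms.
Virtual flowers are `mean + m·√λ_c·axis_c`, so `m = ±2` is the conventional
mean ± 2 SD display; this uses the raw eigen-score SD (standardized scores
differ only by that same constant, so the two readings of "±2 SD" coincide up
to it).

## Evolutionary allometry

Each of the 3K aligned shape coordinates is regressed on centroid size by
OLS; the slopes form the allometric vector β.  Shape scores are projections
of centred coordinates onto β/‖β‖ (the regression-score convention), making
them invariant to any positive rescaling of β.  The observed statistic is the
squared Pearson correlation between shape scores and sizes.  The permutation
test reshuffles the size vector against the fixed configurations and refits
the entire regression each shuffle; because the refitted scores equal
`Xc Xcᵀ s_c` up to a positive scalar, the null distribution is computed from
the S×S Gram matrix — algebraically exact full re-estimation, verified
against a naive refit loop in the tests.  The p-value is the proportion of
null r² strictly larger than the observed r², floored at 1/(m+1); the
(b+1)/(m+1) estimator is available as an option.  The predictor is raw
centroid size by default, with a log-size option.

## Trait quantification

*Tube axis*: for each series order k = 1..25, the centroid of the 10 tube
landmarks (5 midrib + 5 rim) at that order; axis length is the polyline
length.  *Sagittal frame*: the total-least-squares plane of the 25 axis
points; the abscissa is the in-plane chord (proximal→distal endpoint), the
ordinate the in-plane perpendicular signed toward the dorsal side (mean
dorsal-petal tube-midrib landmark relative to the axis centroid).  A
perfectly straight axis has no unique plane; the frame then falls back to
the axis line plus the dorsal reference.  *Tube curvature* is the quadratic
coefficient of the OLS fit v = au² + bu + c of the in-plane axis; positive a
bends dorsally ("upward"), and the trait scales as 1/length under uniform
scaling.  Note the coefficient is defined in the chord-aligned frame: a
curve z = κu² reported in its own (unrotated) frame only measures κ here
when its chord is axis-aligned, which is how the synthetic generator
constructs its centerline.

*Surface triangulation* (scheme `quadstrip-fan/1`): the tube is meshed as
quad strips between azimuthally adjacent landmark columns (each quad split
along its shorter diagonal) with distal cap triangles joining each
primary-IV to the neighbouring rim tops; each lobe is meshed as two strips
zipped between its boundary (rim + half contour) and the midrib spine.
Zipping the spine, rather than a pure centroid fan, guarantees every lobe
landmark (including midrib points) participates in the mesh.  Zero-area
triangles are dropped with a warning count.  *Lobe area ratio* is the
lobe-tagged area over total area.

*Tube dilation* is the centroid size of the 10 order-14 landmarks (mid-tube
transection) divided by the axis length — dimensionless and scale-invariant.
*Lobe recurvation*: the tube-opening plane is the TLS plane through the 10
primary I and IV landmarks (the only template points on the opening), its
normal oriented distally; each petal's bending line runs from its primary-IV
to its primary-III landmark; the trait is the mean angle in degrees.
Degenerate petals are excluded with a warning; a specimen-level geometric
failure is recorded in the trait table and the run continues.

All four traits are rigid-motion invariant; area ratio, dilation and
recurvation are scale-invariant; curvature is homogeneous of degree −1
(property-tested).

## Association and signal statistics

LOD = (n/2)·log₁₀(SST/SSW) across pollination groups — the log-odds form of
the Gaussian one-way likelihood ratio, zero iff group means coincide,
invariant under affine transforms of the trait, +∞ when groups are internally
constant but distinct.  A bare-log variant exists behind a flag.  The
permutation test reshuffles labels (equivalently, values) and counts strictly
larger LODs; SST is permutation-invariant, so only SSW is recomputed per
shuffle.

Blomberg's K uses the BM covariance C (root-to-MRCA branch lengths), the
GLS phylogenetic mean â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x, the observed ratio
(x−â)ᵀ(x−â) / (x−â)ᵀC⁻¹(x−â), and the BM expectation
[tr C − n/(1ᵀC⁻¹1)] / (n−1).  On a star tree K is identically 1 for any
trait; under simulated BM its mean is ≈ 1 on arbitrary trees (both
asserted; the implementation is also cross-checked against an independent
reference implementation in R on a small fixture).  Singular C is ridge-
regularized at 1e-10·tr(C)/n; constant traits raise an error.  The
permutation test shuffles trait values across tips on the fixed tree.

## Ancestral reconstruction

Weighted squared-change parsimony minimizes Σ_branches (Δx)²/length; the
stationarity conditions make each internal value the inverse-branch-length
weighted mean of its neighbours, a sparse SPD linear system solved exactly
(one solve, multiple right-hand sides for the 3K coordinates).  Zero branch
lengths are replaced by 1e-8 × tree height with a warning — small enough not
to shift estimates measurably while keeping the system nonsingular.  Tips
are boundary conditions and are reproduced exactly; the solution is linear
in the tip data (tested).  Species inputs are mean aligned configurations
(full GPA for shape, partial GPA for form); traits and centroid sizes at
ancestors are measured from the form reconstructions, where size is
physical.  For balanced comparative analyses a helper selects the n
specimens per species whose allometry shape scores are closest to the
species median (n = 5 by default, mirroring the standard subset design).

Ancestral pollination labels: ancestors are projected into the extant
morphospace (first 4 PCs), standardized with the extant sample's mean and SD
(ancestors are projections, not refit), and labelled by majority vote of the
k = 5 nearest extant specimens; ties break to the single nearest neighbour.
Reconstruction uncertainty follows a subsampling scheme: in each of 100
repetitions, 3 specimens per species are drawn without replacement, species
means and the reconstruction recomputed, and per-node coordinate-wise SDs
reported.

## Synthetic corollas

The generator is geometric, not statistical: each parameter maps directly to
one measured trait, so every downstream stage has analytic or monotone
ground truth.  The tube sweeps a circular cross-section of radius
`base_radius·(1 + dilation_bulge·sin πt)` along a planar quadratic
centerline written chord-aligned, z(u) = κ·u·(u−U), arc-length parameterized
to `tube_length`; this form has the same second-order coefficient as the
textbook z = κu² parabola but keeps the chord on the abscissa, so the
measured curvature equals κ exactly at zero noise (the tilted form would
confound the coefficient with chord rotation).  Petal midribs sit at 72°
azimuth spacing (ventral at −90°), rims at the midpoints.  Lobes leave the
opening tilted `lobe_bend_deg` from the opening normal (recovered exactly by
the recurvation trait, as the primary I/IV points are coplanar by
construction), with semi-elliptic contours drawn 5% beyond the midrib tip so
contour points never duplicate the primary-III landmark.  `scale` is a global
size factor and `noise_sd` adds isotropic Gaussian landmark noise.

Study-level defaults emulate a 15-species comparative design: a random
ultrametric tree (height 1), 6–16 specimens per species, species parameters
evolved by Brownian motion at rates chosen so excursions stay biologically
plausible (excursions are reflected at hard bounds; scale evolves on the log
scale), specimen-level parameter jitter of ~4% CV plus small additive jitter
on the dimensionless parameters, and landmark noise of 0.15 mm (a few voxels
of digitization error).  Pollination labels follow a documented synthetic
convention: curvature ≥ 0.015 mm⁻¹ → hummingbird; else tube length/radius ≥ 8
→ moth; else bee.  Named fixtures (`null`, `allometric`,
`two-clade-curvature`) bake in seeds for deterministic tests.

What synthetic tests do not show: real corollas have asymmetries, petal
fusion variation, non-circular cross-sections and correlated (non-isotropic)
digitization error, none of which the generator produces.  Passing tests
establish that the estimators recover known ground truth under the stated
model and that the permutation tests are calibrated under their nulls — not
that the biological conclusions drawn from any particular real dataset are
correct.

## Problem sizes and numerical tolerances

The test suite uses desk-scale problems chosen to exercise every code path:
GPA/PCA on ensembles of 5–170 specimens, permutation tests at 200–10,000
shuffles, type-I error calibration over 200 null datasets at 1,000
permutations, and 500 BM replicates for the K calibration.  Key tolerances:
GPA convergence 1e-8 (RMS consensus change); rotation properness 1e-10;
curvature recovery 2% (discretization); dilation on ideal cylinders 1e-9;
recurvation 1°; areas 3% (polygonal approximation of curved boundaries);
parsimony vs oracle 1e-6; collinearity fallback threshold 1e-9 (relative
singular value).

## Known limitations

- No sliding semilandmarks: secondary landmarks are taken as equally spaced
  upstream; no bending-energy or Procrustes-distance sliding is performed.
- Tree inference is out of scope; trees are inputs.  Distributions of K over
  tree replicates can be obtained by mapping `blomberg_k` over a tree list.
- The LOD statistic assumes exchangeable specimens; with strong within-
  species structure its permutation null mixes within- and between-species
  variation.
- Surface areas are landmark-polygon areas, not full mesh areas of the
  underlying scan surfaces; with 415 landmarks the discretization error is a
  few percent and cancels partially in the lobe/total ratio.
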