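# Methods

## Reference space and coordinate conventions

The common reference volume follows the conventions of the 10 µm mouse
brain template: x runs anterior→posterior, y superior→inferior, z
left→right, origin at the anterior-superior-left corner; the full-scale
grid is 1320 × 800 × 1140 voxels. Voxel indices are 0-based and each
voxel is the half-open cube [i, i+1) per axis, so continuous coordinates
are binned by `floor`. The left hemisphere is z < n_z/2 (low z is left
because the origin sits at the Left corner), and mirroring is the
reflection z′ = n_z − 1 − z about the grid's center plane — an involution
that keeps indices in bounds. Region ids are opaque integers organized in
a single-rooted acyclic hierarchy; cortical layer membership is carried
as an explicit tag (`1, 2/3, 4, 5, 6a, 6b`) rather than parsed from
names, with an acronym-suffix parser as a fallback (names like `CA1`
whose stem ends in a digit are inherently ambiguous for such a parser,
which is why the explicit tag takes precedence). Alternative
parcellations (e.g. an ARA-style and a EUAL-style labeling) share the
identical grid and template and differ only in annotation + hierarchy;
`ReferenceSpace.with_parcellation` swaps them without touching geometry.

## Section preparation

Sections are numbered `s001, s002, …` in the user-asserted
anterior→posterior order. The downsampling factor is shared by the whole
series: n = max over sections of ⌈√(h·w / 15·10⁶)⌉, floored at 1. The
ceiling is taken per image so the 16-megapixel input bound of the
registration tools always holds; on images whose sides are not divisible
by n the output can marginally exceed the 15-megapixel working budget
(by at most (h+w)/n + 1 pixels) but never reaches 16 MP. Subsampling
keeps every n-th pixel starting at index (0, 0) — deterministic phase 0.
Orientation fixes (rotations by multiples of 90°, mirror flips) are
user-declared per section, never auto-detected.

## Registration model

A section image is anchored by three 3-vectors in voxel units: o (the
top-left pixel's position), u (spanning the full image width) and v (the
full height). Pixel p = (pₓ, p_y), measured from the top-left corner with
x rightward and y downward, maps to o + (pₓ/width)·u + (p_y/height)·v.

Nonlinear refinement comes as marker pairs between the section and its
anchored template plane, both expressed in the section's pixel frame.
The deformation is a piecewise-affine interpolant over a Delaunay
triangulation of the section-side marker points with the four image
corners added as fixed points: continuous, exact at every marker, the
identity when no markers are given. The field is evaluated directly in
the section→template direction, so the cleaned segmented image — which
shares the registered image's geometry exactly — can be pushed into the
volume without rendering a deformed template first. The interpolant is
evaluated by exact barycentric interpolation per simplex; a per-triangle
affine solve is used as an independent oracle in the tests. Points that
warp outside the image rectangle are clamped to it and counted (not
dropped), preserving the pixel-count ledger. Whether the upstream GUI's
own interpolant is piecewise-affine is not something this package
asserts; equivalence holds for the file dialects it reads and writes.

## Segmentation post-processing

Classifier output labels 1/2/3 are recoded to gray values 255 (axon),
0 (background), 129 (soma); the recoding is idempotent (already-recoded
images pass through). Objects are connected components over the union of
soma and axon pixels — one joint rule, with each surviving pixel's
original label restored — where two pixels are neighbors iff their
squared Euclidean distance is ≤ 3. In 2D this admits diagonal steps
(squared distance 2) and excludes two orthogonal steps (4), i.e.
8-connectivity; the threshold value 3 generalizes to a 3D neighborhood.
Components of fewer than 12 pixels are relabeled background. Cleaning is
idempotent and never increases the labeled-pixel count.

## Voxelization and curation

Each labeled pixel's **center** (col + 0.5, row + 0.5) is pushed through
warp-then-anchor and floor-binned; using centers makes voxel-center
round-trips exact and is symmetric under the half-open cube convention.
Counts accumulate per voxel: a voxel of value 100 holds 100 segmented
pixels. Pixels that land outside the reference grid are dropped and
reported, so per experiment

  Σ voxel counts + removed pixels + out-of-grid drops = raw labeled pixels

holds exactly; the pipeline manifest records this ledger per section and
aborts if it ever breaks. Section thickness is not spread across
multiple 10 µm planes — each pixel contributes to exactly one voxel on
its anchored plane, and inter-section gaps remain unfilled (no
between-section interpolation). Voxels hit by several sections sum their
counts; assembly is therefore order-independent. Curation moves soma
voxels whose annotation is not within the expected nucleus into the axon
cloud (counts added), reflecting that soma labels outside the injection
nucleus are false negatives of neurite signal. Hemisphere splitting
partitions at z < n_z/2; mirrored right-hemisphere voxels that collide
with existing left voxels sum. When several populations occupy one
coordinate, the displayed population is the one with the highest axon
count there, ties broken lexicographically by experiment id; population
colors are auto-assigned from a maximally hue-spaced palette and can be
overridden.

## Analytics

Flatmap projection **sums** voxel counts over depth into each voxel's
flat pixel (the flat intensity is a segment count), whereas subcortical
views are **maximum** projections — the two rules are deliberately
different and both stated here. Cortical coverage is (flat cortex pixels
with intensity > 0) / (all flat cortex pixels); the whole cortical
surface is the default denominator and the threshold (> 0) is
configurable. Layer distributions normalize axon counts per layer tag to
100 % within the chosen area; groupings like "layer 5 or 6" are formed
downstream by summing bins. An area with zero axon signal yields an
all-zero profile with a warning, not a division error. Maximum
projections overlay three layers: per-pixel template maximum along the
axis, boundary contours of the projected nucleus sub-region labels
(projection rule: first nonzero label along the axis — any deterministic
rule works for boundary extraction, and this one is independent of
label ids), and the per-pixel maximum of soma counts. Section overlays
are emitted as SVG 1.1: region-colored filled contours with black
boundary strokes and segmented pixels drawn as black 1-px rectangles
(subsampled above a cap to keep files bounded).

## Integration

The population medoid is the occupied voxel minimizing the
count-weighted sum of Euclidean distances to all occupied voxels
(k-medoids with k = 1); count weighting is the default and an unweighted
variant (unique voxels) is available, since either reading is defensible.
Ties resolve to the lexicographically smallest coordinate. The
membership radius is 1.5 × the maximum medoid-to-soma distance — the
factor compensates incomplete sampling by the tracer — and the
membership ball is **closed** (a soma exactly at the radius is a
member). Terminal points of member reconstructions are floor-binned with
unit counts. For SWC morphologies, terminal points are the leaf nodes of
axon-typed (type 2) subtrees; a branch-order criterion would be an
alternative reading, and pre-extracted point lists can be supplied via a
JSON dialect to bypass the choice. Bulk-experiment matching picks the
catalogue entry whose injection centroid is nearest the medoid. Overlap
maps assign each flat pixel exactly one of four states (overlap /
population-only / other-only / neither); fractions are reported over the
**targeted** pixels within the area of interest by default, so the three
states sum to 1, with an `denominator="area"` mode dividing by all area
pixels instead — both normalizations are meaningful and the default is
the one that makes the states a partition of the reported mass.
Distances are computed in voxel units; the grid is isotropic, so this is
equivalent to µm up to the fixed 10 µm scale.

## Synthetic studies

The generator builds a 132 × 80 × 114 fixture space (≈1/10 linear scale,
identical axis semantics): a six-layer cortical shell subdivided into
areas mirrored across the midline, a "VPM"-role nucleus with a "PO"
neighbor per hemisphere, and a generic remainder region, all wrapped in
a single-rooted hierarchy with explicit layer tags. Experiments plant a
rectangular soma blob inside the nucleus and axon blobs inside chosen
cortical layer regions on 10 coronal planes by default, at 4 pixels per
voxel, plus decoy objects of 1–11 pixels that straddle the cleaning
threshold (placed clear of real signal so the cleaning step removes
exactly them). With a nonzero warp magnitude the generator defines a
smooth two-bump Gaussian displacement field calibrated to the requested
peak magnitude, samples a 5 × 7 marker grid from it, and renders section
pixels by fixed-point inversion of the forward field; the pipeline
recovers the geometry through its own piecewise-affine fit of those
markers, so recovery error reflects genuine interpolation and rounding
error rather than a shared code path. At zero warp the recovery of the
planted voxel clouds is exact; at 8 px peak warp the recovered support
overlaps truth with Jaccard ≳ 0.95 on the default fixture. All
generators are pure functions of (parameters, seed).

What the fixtures do **not** emulate: stained-tissue appearance and
classifier errors (the generator emits clean label images), anisotropic
section thickness effects, registration error in the anchor vectors
themselves, and the anatomical shapes of real nuclei. Passing tests
therefore validate the geometry, bookkeeping and statistics of the
pipeline — not the upstream classifier or the human registration step.

## Problem sizes and numerical choices

Default test fixtures use the 132 × 80 × 114 space with 10 sections of
456 × 320 px — small enough that the full suite runs in seconds while
every code path (warping, cleaning, curation, mirroring, flatmaps)
is exercised. Warp exactness at markers is asserted to 1e-9 px and
continuity across triangle edges to 1e-6; medoid and cleaning oracles
are exact comparisons. Degenerate inputs are defined rather than left to
chance: empty marker sets give the identity warp, empty segmentations
give empty clouds, empty layer profiles and overlap masks warn instead
of raising, and a single-voxel soma cloud has radius 0 (a floor of 2
voxels is applied only inside the synthetic morphology generator so the
membership ball remains usable there).

## Known limitations

- No interpolation between section planes; voxel clouds are sparse along
  the anterior-posterior axis by construction.
- The nonlinear warp's byte-level equivalence with the upstream GUI's
  renderer is not guaranteed, only dialect-level compatibility.
- The acronym-suffix layer parser cannot distinguish layer digits from
  digit-final region names; supply explicit layer tags for such regions.
- Flatmap lookups are consumed, not derived: building a cortical
  flattening from scratch is out of scope.
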