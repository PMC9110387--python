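# Methods

This note records the models, conventions and numerical choices behind
`combscan`, and what the phantom-based validation does and does not
demonstrate.

## Representations and coordinates

A scan is a regular voxel grid of min–max-normalized attenuation values
in [0, 1]; voxel `(i, j, k)` (0-based, `k` the slice axis) has its
center at `origin_mm + (i, j, k) · spacing_mm`. Shape-only operators see
the comb as a constant-density solid through a signed Euclidean distance
field, computed as an exact (not chamfer) distance transform of the
binarized grid — negative inside, positive outside, each voxel's
distance taken to the nearest voxel center of the opposite phase, so a
small-grid brute-force oracle can match it exactly. The default
binarization threshold is a fixed iso level (no automatic thresholding)
so results are deterministic; for the phantoms, whose wax encodes at
0.475, tests use 0.2. Surfaces are marching-cubes triangulations of the
SDF zero level set, oriented so face normals point outward, cleaned of
degenerate faces. I/O goes through established readers (tifffile for
slice stacks, SimpleITK for NRRD, nibabel for NIfTI); TIFF stacks carry
no world metadata, so spacing/origin are user-supplied. Anisotropic
spacing is accepted at the I/O layer, but analysis operators require
isotropic voxels and reject otherwise, matching the isotropic ~0.1 mm
voxels of comb scans.

## Morphology

Offsets by a Euclidean ball of radius `r` act on the SDF: dilation keeps
voxels with distance ≤ `r`, erosion keeps voxels with interior depth
strictly > `r`. The asymmetric tie rule makes erosion the exact
complement-dual of dilation on the grid and makes both match discrete
Minkowski operators with the Euclidean ball footprint voxel-for-voxel —
the property the oracle tests rely on. The grid boundary is treated as a
clipping window, not as solid boundary (erosion does not eat inward from
the grid edge). Compositions (closing, opening) run internally on binary
masks with one distance transform per offset and are redistanced once at
the end; closing pads the grid by `ceil(r/h) + 2` voxels so the
intermediate dilation cannot clip, then crops back so the result can be
Boolean-combined with its input. Idempotence of closing/opening holds
exactly at mask level.

## Curvature

Curvature is estimated by local quadric fitting at a behaviorally
motivated scale: the neighborhood radius (default 15 mm) corresponds to
the region a worker bee can sense tactually, and is gathered as a
*mesh-geodesic* ball (shortest edge paths) rather than a Euclidean ball
so the opposite comb sheet 7–10 mm away through air is never captured.
Each neighborhood is expressed in a frame whose z axis lies along the
*inward* vertex normal (area-weighted average of incident face normals);
with that orientation the Monge-patch shape operator gives positive
principal curvatures on a convex solid, and the quadric
`z = ax² + by² + cxy + dx + ey` (no constant term; the surface passes
through the vertex) reproduces analytic test patches exactly. The
tangent basis projects the world axis least aligned with the normal, so
near-planar patches get world-aligned coefficients. Fits use an SVD
conditioning check (condition number > 1e8 → degenerate, value inherited
from the nearest valid vertex and flagged). Local averaging is one-ring
mean smoothing, default 2 rounds — the field is "locally averaged"
without a prescribed count, and 2 rounds suppress tessellation noise
while moving the area-weighted channel means by well under 1%.
Histograms weight each vertex by one third of its incident triangle
area.

## Geodesics

Travel cost solves `|∇u| = 1/s` by fast marching on the 6-neighborhood,
with the upwind update promoted to second-order differences where two
frozen upwind values are available; on the cylinder-shell benchmark this
brings the error from ~7% (first order, 0.4 mm voxels) to under 1%. Fast
marching was chosen over the heat method because it is deterministic and
directly comparable to a Dijkstra oracle on the voxel graph. The speed
field is the density value clamped below at 1e-3 (density can vanish in
pores, but the speed-inverse must stay finite); voxels outside the
domain mask stay at +inf and are counted. Build direction is the
re-normalized mean of per-voxel *unit* gradients — gradient magnitude
varies with the metric, but direction is the quantity of interest — with
dispersion `1 − |mean resultant|`. Paths descend through lower-cost
neighbors (26-connectivity), which keeps tracing robust on thin shells
at the cost of slight zigzag (length within 10% of `u`).

## Spectral analysis and skeletons

The default Laplacian is cotangent-weighted with a lumped (barycentric)
mass matrix; a uniform graph Laplacian is kept for closed-form oracle
spectra. Eigenpairs come from dense LAPACK below ~1500 vertices and
shift-invert Lanczos (anchored at −1e-3, where `L + σM` is definite)
above; eigenvector signs are fixed deterministically (first
above-tolerance component positive). Segmentation bins the Fiedler
vector into equal-mass quantile ranges — deterministic, and faithful to
selecting "values within a small range" — with per-segment planes from
the first two principal components of member vertex positions. Note a
geometric caveat validated in the tests: the surface-point PCA plane of
a segment is the sheet face only while the segment's in-plane extent
exceeds ~1.7× the slab thickness; thin bands on thick slabs flip the
plane toward the band direction.

Curve skeletons link isocontour-component centroids with Prim's MST
(Euclidean weights, ties to the lowest node index; Kruskal is the test
oracle). Contours are extracted as connected sets of mesh edges crossing
a level, with crossing points linearly interpolated; components with
fewer than 3 points are dropped, and short twig branches can be pruned.
The driving scalar defaults to the Fiedler vector, but any per-vertex
field may be supplied: for the construction-order medial tree the
package uses geodesic distance from the substrate on the *closure* of
the comb (cells filled, so the skeleton tracks the lobe rather than
individual walls, computed at 2× downsampling for economy). Distance
fronts necessarily split where the lobe branches, whereas sublevel sets
of the Fiedler vector of a branched sheet can stay connected along its
outer margin and never produce a second contour component — a failure
mode we observed directly on Y-shaped phantoms.

## Cell extraction, tilt and gravity

The negative space of a section is the Boolean difference between its
10-mm-ball closure and itself; iterative opening (radius growing from
one voxel in one-voxel steps until the 6-connected component count is
unchanged for two consecutive radii) severs residual connections, and
components smaller than 20 voxels are discarded as slivers. Cell
extraction expects the *constructed comb only*: if the attachment
substrate is left in the solid, the closure creates a junction fillet
that survives as a spurious component — on real scans the
material-banding step isolates comb first, and the phantom pipeline does
the same with the ground-truth substrate mask.

Per-cell frames are covariance eigenvectors ordered by descending
eigenvalue; a cell whose top two eigenvalues differ by less than a
factor 1.2 is flagged degenerate. The median plane is fit by SVD to cell
base points, where a cell's base is the deep end of its principal axis —
of the two extreme ends, the one farther inside the closed comb. (An
earlier rule, "the voxel with minimal closure-SDF", fails for cells near
lateral faces, where the lateral exterior is closer than the mouth.)
Principal axes are then flipped to point away from the plane (centroid
side test). Tilt is reported as the angle between the principal axis and
the *plane normal* — equivalently 90° minus the angle to the plane — so
a canonical comb reads ~13°. Gravity is minus the robust mean
(componentwise median, re-normalized) of the unit in-plane projections
of the axes: cells tilt upward, against gravity. Cells touching the
volume boundary are excluded from tilt/gravity statistics (clipped
volumes bias PCA), and near-zero projections (median below 0.02) raise
"tilt unresolvable" rather than returning a noise direction.

Metrics: depth is the caliper extent along the principal axis plus one
voxel; width is the *minimal* in-plane caliper over directions of the
minor plane (rotating calipers on the convex hull) — for a hexagonal
cell that is the flat-to-flat width measured in the field. The PCA minor
axes themselves are arbitrary under the hexagon's six-fold symmetry, so
a mean caliper across them would carry an intrinsic ~0.3 mm positive
offset that no resolution refinement removes; the minimal caliper
converges.

## Materials

Calibration is a least-squares line through (normalized value, known
density) references, strictly increasing, global per scan (no spatial
field correction). Bands are half-open `(lo, hi]` so adjacent bands
partition cleanly, with the tie going to the upper band; no
partial-volume correction is applied — boundary voxels are assigned
whole, a known bias of attenuation-based density estimation. Honey
volume is the honey-band volume in ml, optionally intersected with
extracted cell interiors.

## Build order

The construction walk starts at the leaves of the medial tree and moves
back along decreasing geodesic distance from the substrate; "branch"
means a skeleton node of degree ≥ 3. Each chain between branch points is
a timeline segment with a build direction (mean unit gradient over its
voxels, voxels assigned to the nearest skeleton node) and a gravity
re-estimated from its member cells (fewer than 5 cells → inherited from
the parent, flagged). Siblings of one parent are indistinguishable to
the heuristic and are ordered by ascending mean geodesic value, flagged
as ties. A long unbranched lobe built under changing conditions (a hive
rotation) carries no branch point at which to re-estimate anything, so
chains may optionally be subdivided at a maximum arc length; the
rotated-phantom validation uses 25 mm, about the span of a growth
episode between rotations.

## The phantom generator

Phantoms emulate the canonical comb geometry: double-sided sheets of
point-up hexagonal cells (one vertex toward the substrate), interior
edge 2.5 mm, walls 0.75 mm, depth 10.5 mm, interface septum of wall
thickness, lobe spacing 8.5 mm, cells modeled as hexagonal prisms
*rotated* by the tilt angle (13°) about their base centers toward minus
gravity and clipped by the septum — rotation, not shear, so the caliper
depth along the recovered PCA axis equals the planted depth. Warps
cover a cylindrical bend and a saddle (coordinate transforms with
analytic inverses), an L-bend and a Y-branch (multiple flat panels with
rotated frames), and a mid-build gravity rotation (stacked panels with
different planted gravities). The Y-branch arms default to unequal
lengths; a perfectly symmetric Y makes the Fiedler vector antisymmetric
across the arms, which is a legitimate spectral outcome but a degenerate
test case. Materials encode as `value = density/2` (wax 0.95, substrate
1.19, honey 1.4 g/cm³ → 0.475, 0.595, 0.70), so the phantom's true
calibration line has slope 2 and intercept 0. Honey fills a contiguous
run of cells (seeded start) up to a volume budget, the last cell
partially to the exact fraction. Ground truth records everything the
analyses are meant to recover; the same spec and seed reproduce the
volume bitwise.

What the phantoms do *not* emulate: scanner noise and beam-hardening,
partial-volume blur at material boundaries, irregular or merged cells,
wall-thickness variation, drone/queen cells, and curved interfaces
within a single panel. Passing the recovery suite therefore demonstrates
correctness of the geometry pipeline under clean conditions, not
robustness to acquisition artifacts.

## Problem sizes

Validation runs use phantoms of 24–74 cells at 0.2–0.35 mm spacing
(1–4 M voxels), analytic meshes of 5–70 k vertices, and 16³ random grids
for the voxel-exact morphology oracles — sizes chosen so each
generate→analyze→compare loop closes in seconds to a couple of minutes
while every wall remains ≥ 2 voxels thick and every cell ≥ 10³ voxels.
The full-resolution workflow on real scans is identical code at larger
grids; the heavy operators (geodesics, curvature) are typically run
after 2× downsampling, as is standard for teravoxel-scale
reconstructions.
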