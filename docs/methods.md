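# Methods

This note documents the models, numerical choices and known limitations of
`sfproj`. It covers what each stage computes, the parameters that matter
(with units and defaults), what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reasonable
construction exists.

## Orientation conventions

A joint pose is stored as the 3×3 matrix whose **rows** are the endpoints of
the distal frame's X, Y, Z axes expressed in the proximal frame
(`Orientation.m`). This is the transpose of the conventional column-axes
rotation matrix, which is exposed as `Orientation.rotation`; the row form is
used because those rows are exactly the points the SFP plots. Homogeneous
transforms follow the convention that `^A T_B` maps coordinates expressed in
frame B into frame A, under which the three-transform chain composes by
plain matrix multiplication and the rotation block of `^dACS T_pACS` has the
row-endpoint property above.

Euler angles are **degrees** at every public interface (radians internally).
The default sequence is intrinsic Z-Y-X with Z as the flexion/extension
axis, a common biomechanical assignment, but the sequence and the
intrinsic/extrinsic flag are fully configurable (`EulerSpec`) because
conventions vary across studies and the literature rarely states the
composition convention explicitly. Quaternions are canonicalised to the
`w ≥ 0` hemisphere (first nonzero vector component positive when `w = 0`),
so every rotation has a unique representative; consequently `rotation_axis`
always reports a positive angle in (0°, 180°] with the sign carried by the
axis, and the identity has no axis (an error, not a sentinel).

Validation tolerance for orthonormality and determinant is `1e-9`:
double-precision composition of a chain of ten rotations accumulates error
around `1e-15`, so `1e-9` separates genuinely malformed input from numerical
noise with six orders of margin. Note that a homogeneous transform's 4×4
transpose equals its inverse only when the translation is zero; `invert`
always applies the exact rigid inverse (`Rᵀ`, `−Rᵀt`). The final joint
*orientation* is unaffected by this distinction because rotation blocks
multiply independently of translations.

## Boundary fitting

The boundary polygons are fitted by patch occupancy on a recursively
subdivided icosahedron. Defaults: 3 subdivisions = 1 280 triangular patches
(near-equal solid angles, max patch width ≈ 9.4° of arc), dilation 0 rings
(tight fit). Patches containing at least one trace point are marked
occupied, dilated by the requested number of neighbour rings, and the outer
perimeter of the occupied region is extracted by chaining the directed
boundary edges (region kept on the left) into loops. When several loops
exist, the outer one is identified by the sign of the spherical fan sum
around the region centroid: the outer loop winds positively, holes
negatively; holes are absorbed (the polygon is the filled outer boundary).
A region that covers the whole grid, or whose loops all wind negatively
(e.g. a band spanning more than a hemisphere), raises an
ambiguous-boundary error recommending a finer grid.

Two consequences of this construction are worth knowing:

* **Containment is guaranteed.** Every input point lies inside its polygon
  at any resolution. If the occupied region is edge-disconnected at the
  requested dilation (sparse sampling), it is grown one ring at a time
  until connected so that a single perimeter exists; the effective dilation
  is recorded in the SFP metadata. The tight fit therefore adapts to
  sampling density rather than failing.
* **Areas are biased outward by O(perimeter × patch width).** A polygon
  made of whole patches overshoots the underlying region; the relative
  error decays linearly with patch width (measured: ~8% at 1 280 patches,
  ~4% at 5 120, ~2% at 20 480 for an octant-sized region). Comparisons
  between SFPs should use a common resolution.

Point-in-polygon tests count great-circle crossings along the geodesic from
the stored interior reference point to the query. Queries within `1e-9`
radians of an edge are classified inside (closed region), which keeps
boundary-defining samples inside their own polygon. If the test geodesic
grazes a polygon vertex within `1e-12` radians the crossing parity is
ill-defined; the reference point is then deterministically jittered
(`1e-5`–`3.6e-4` radians, far below patch scale) and the test retried. A
query antipodal to the reference point has no unique geodesic and raises an
error rather than guessing. Polygon areas use the Van Oosterom–Strackee
signed-excess fan from the interior point; the magnitude of the fan sum is
the enclosed solid angle on the interior side regardless of vertex storage
order.

## Pose checks and the false-positive problem

`check_pose` reports, per axis, whether the pose's axis endpoint lies in
its polygon. All-inside is **necessary but not sufficient** for
reachability: three endpoints can each lie inside its region yet originate
from different sampled poses, so an infeasible pose can pass. This is an
intrinsic property of the representation, not an implementation artifact.
`check_pose_path` mitigates it by requiring connectivity to a known-viable
start pose through the sampled data: a graph is built over the dataset
(plus start and target) with edges where the rotational geodesic distance —
the angle of the relative rotation, computed from quaternion dot products —
is at most `step_max` (default 10°), keeping at most `k` (default 6)
nearest such neighbours per node, and the target is viable iff connected.
The check is a sampling-density-dependent heuristic: too small a
`step_max` fragments a genuinely connected range, too large a one bridges
genuinely disjoint regions. It is deliberately conservative in that edges
never exceed `step_max`.

## Coverage accounting

The live-feedback coverage heatmap is modelled as pass counts on the same
icosphere grid. One *pass* is a maximal run of consecutive trace samples in
a patch; re-entry after at least one sample elsewhere is a new pass.
Display intensity is `min(count, 3)/3`, saturating after three independent
passes — the rule used to declare a region of pose space adequately
sampled. Streaming state (current dwell patch) persists across calls so
chunked input is equivalent to a single stream.

## Landmark frame fitting

*Plate frames* are fitted from points placed on the three faces meeting at
the plate's reference corner (`face_x/face_y/face_z` groups, ≥3
non-collinear points each; many well-spread points filter digitisation
noise). Each face gets a least-squares SVD plane; normals are signed
outward (away from the landmark centroid, a rigid-motion-invariant rule);
the origin is the intersection of the three fitted planes; the axes are
exactly orthogonalised. *Bone frames* use lines fitted through ordered
points along the proximal and distal articular edges (first-to-last order
fixes the direction sign); the long axis joins the edge-line midpoints, the
second axis follows the proximal edge direction, the third completes the
right-handed triad, origin at the proximal midpoint. Which anatomical
motion each axis represents is a labelling convention left to configuration,
since it varies by taxon and study.

*Orthogonalisation* uses recursive cross-product averaging: cycling through
the axes, each axis is replaced by the normalised average of itself and the
sign-matched cross product of the other two, until the maximum pairwise
|dot| is ≤ `1e-12` (cap 10 000 iterations; the residual decreases
monotonically and convergence is quadratic near orthogonality). Inputs with
any pairwise |dot| ≥ 0.5 are rejected as not recognisably a frame;
left-handed triads are corrected by flipping the third axis (or rejected,
per flag). One caution: because the correction applied to one axis mixes
the errors of the other two, an axis can move by up to roughly 1.5× the
input skew (measured worst case 3.1° for 2° skews) — the scheme is exact
but not displacement-optimal; a polar decomposition would move axes less
but is not what this pipeline specifies.

## Synthetic data: what it does and does not emulate

`generate_rom` produces the canonical study regimes: single-DoF arcs,
independent 2-DoF (±30°/±15° by default) and 3-DoF Euler boxes, and coupled
DoF where the half-range of one axis is a piecewise-linear function of
another axis's angle (the regime in which flexion is locked near the null
pose and freed by a large rotation about another axis). Sampling is a
regular grid (default 5° steps; 1° for desk-scale arc measurements) or
uniform-random with a seed; identical spec + seed is byte-identical.

`simulate_session` inverts the processing chain to place a rigid 4-marker
tree (non-coplanar, ~40 mm span) in the base frame for every ground-truth
pose, using rig constants of a few centimetres with non-trivial rotations
so that chain errors cannot cancel, then adds isotropic Gaussian marker
noise (default sd 0.1 mm, a typical optical motion-capture residual).
Passive torque is a piecewise power-law spring per Euler axis: zero up to a
soft-limit onset (default 25°), `stiffness·excess^exponent` beyond
(defaults 0.5 N·mm/deg³, exponent 3) — the simplest nonlinear stand-in for
soft-tissue stress–strain behaviour. Audio-feedback logic is reduced to its
decision rule: below a threshold torque magnitude (default 20 N·mm)
silence, between threshold and upper limit (default 200 N·mm) a pitch
fraction `(|τ|−thr)/(upper−thr)`, above it saturation. These torque numbers
are user-supplied parameters with documented defaults, not measured
constants.

The generators deliberately do **not** emulate: camera projection, marker
identification/occlusion patterns (occlusion is injected explicitly in
tests), joint translation, soft-tissue hysteresis or time-dependence of
torque, or operator behaviour. Passing tests therefore demonstrate the
correctness of the geometry and the processing chain under the stated noise
model — not robustness to every pathology of real capture sessions.

## Degenerate inputs and tie-breaks

* Empty orientation sets are rejected at construction.
* A single-point cloud yields the degenerate one-patch polygon.
* Identity rotation: no rotation axis (error).
* Coincident bone-edge midpoints, collinear plane points, coplanar marker
  trees: explicit errors naming the degeneracy.
* Mocap frames with fewer than three visible markers are dropped with a
  warning; a one-of-four occlusion is solved (three-point Procrustes) and
  flagged.
* CSV numeric precision is 12 significant digits (round trips below 1e-9);
  JSON carries full doubles.

## Problem sizes

The test-suite and acceptance computations run at desk scale, chosen so the
geometry is fully resolved: 61-pose single-DoF arcs (1° grid), 325-pose
2-DoF grids (2.5°), a few hundred to 4 000 random poses for 3-DoF and
coupled regimes, 1 000 frames for the full-chain recovery property,
20 000-sample Monte-Carlo area estimates, and 100-seed Monte-Carlo runs for
the fitting error bounds. All are the package's own defaults for
demonstrating the stated invariants.

## Known limitations

* The membership test admits false positives by construction; the path
  check reduces but cannot eliminate them and its verdict depends on
  sampling density and its two parameters.
* Occupancy-grid polygons over-cover by one patch at the margins; areas are
  upper bounds at a given resolution.
* Only rotational DoF are represented; joint translations are out of scope.
* The boundary is fitted automatically; there is no interactive editing of
  patches, and the reach-cone family of boundary constructions is not
  implemented.
* Coupled-DoF coverage of the sampling box uses rejection, so extreme
  coupling rules thin the sample rather than reshaping the proposal.
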