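"""The spherical frame projection (SFP).

An orientation dataset — rotation matrices of the distal anatomical coordinate
system (ACS) expressed in the proximal ACS — is traced on the unit sphere by
plotting each matrix row as a point: the endpoints of the distal X, Y and Z
axes.  The SFP bounds each of the three resulting point clouds with a
spherical polygon, giving an intuitive picture of a joint's rotational range
of motion, including interactions between degrees of freedom.

Boundary polygons are fitted automatically by patch occupancy on a subdivided
icosahedron grid followed by an outer-perimeter walk.  The module also
provides pose viability checks (per-axis polygon membership, explicitly a
necessary-but-not-sufficient test), a path-connectivity check that guards
against the false-positive poses a pure membership test admits, and a
coverage heatmap accumulator with three-pass saturation mirroring live
feedback during range-of-motion trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import (
    AmbiguousBoundaryError,
    UnanchoredStartError,
    ValidationError,
)
from .orientations import Orientation, OrientationSet, to_quaternion, validate
from .spherical import SphereGrid, SphericalPolygon, default_grid

AXES = ("X", "Y", "Z")


# ---------------------------------------------------------------------------
# Frame traces
# ---------------------------------------------------------------------------


@dataclass
class FrameTrace:
    """Three labelled sphere point clouds: one per distal frame axis.

    ``clouds["X"][i]`` is row 0 of orientation i — the X-axis endpoint — and
    likewise for Y and Z, so all three clouds have the same length and, per
    index, form an orthonormal triad.
    """

    clouds: dict[str, np.ndarray]
    source: OrientationSet | None = None

    def __len__(self) -> int:
        return len(self.clouds["X"])


def frame_trace(data: OrientationSet) -> FrameTrace:
    """Project an orientation dataset onto the sphere.

    Each rotation matrix contributes its three rows to the X, Y and Z clouds
    respectively.

    Raises
    ------
    ValidationError
        Naming the offending index if any member fails the proper-rotation
        check.
    """
    for i, o in enumerate(data):
        rep = validate(o.m)
        if not rep.ok:
            raise ValidationError(f"orientation {i} is not a proper rotation")
    mats = data.matrices()
    return FrameTrace(
        {"X": mats[:, 0, :].copy(), "Y": mats[:, 1, :].copy(), "Z": mats[:, 2, :].copy()},
        source=data,
    )


# ---------------------------------------------------------------------------
# Boundary fitting
# ---------------------------------------------------------------------------


def fit_boundary(
    points: np.ndarray,
    resolution: int = 1280,
    dilation: int = 0,
    grid: SphereGrid | None = None,
) -> SphericalPolygon:
    """Fit a spherical boundary polygon around a point cloud.

    Patches of a subdivided-icosahedron grid containing at least one point
    are marked occupied, optionally dilated by ``dilation`` rings of
    neighbouring patches, and the outer perimeter of the occupied region is
    extracted as an ordered vertex loop.  Every input point ends up inside
    the returned polygon.

    If the occupied region is disconnected at the requested dilation it is
    grown one ring at a time until connected, so sparse clouds still yield a
    single containing polygon; the effective dilation is available from the
    polygon's metadata on the :class:`SFP` that wraps it.

    Parameters
    ----------
    points:
        (n, 3) unit vectors.
    resolution:
        Minimum number of grid patches (rounded up to a subdivision level;
        default 1280 = 3 subdivisions).
    dilation:
        Number of neighbour rings to grow the occupied region by (default 0,
        a tight fit).
    grid:
        Pre-built grid; overrides ``resolution``.

    Raises
    ------
    AmbiguousBoundaryError
        If the occupied region covers the whole grid or has no single
        consistent outer perimeter (e.g. a band spanning more than a
        hemisphere); a finer resolution usually resolves it.
    """
    p = np.atleast_2d(np.asarray(points, float))
    if len(p) == 0:
        raise ValidationError("cannot fit a boundary to an empty point cloud")
    g = grid if grid is not None else default_grid(_level_for(resolution))
    mask = np.zeros(g.n_patches, dtype=bool)
    mask[g.locate(p)] = True
    mask = g.dilate(mask, dilation)
    # grow until edge-connected so one perimeter contains all points
    extra = 0
    while len(g.connected_components(mask)) > 1 and extra < 16:
        mask = g.dilate(mask, 1)
        extra += 1
    if mask.all():
        raise AmbiguousBoundaryError(
            "occupied region covers the entire grid; use a finer resolution"
        )
    loops = _boundary_loops(g, mask)
    interior = _interior_reference(g, mask)
    poly = _select_outer(loops, interior, g)
    poly.effective_dilation = dilation + extra
    return poly


def _level_for(resolution: int) -> int:
    for s in range(8):
        if 20 * 4**s >= resolution:
            return s
    raise ValueError("resolution too large")


def _boundary_loops(grid: SphereGrid, mask: np.ndarray) -> list[np.ndarray]:
    """Directed boundary edges (region on the left) chained into vertex loops."""
    succ: dict[int, list[int]] = {}
    n_edges = 0
    for f in np.flatnonzero(mask):
        fa, fb, fc = grid.faces[f]
        for e, (a, b) in enumerate(((fa, fb), (fb, fc), (fc, fa))):
            if not mask[grid.adjacency[f, e]]:
                succ.setdefault(int(a), []).append(int(b))
                n_edges += 1
    loops = []
    while succ:
        start = next(iter(succ))
        loop = [start]
        cur = succ[start].pop()
        if not succ[start]:
            del succ[start]
        for _ in range(n_edges + 1):
            if cur == start:
                break
            loop.append(cur)
            nxts = succ.get(cur)
            if not nxts:  # open chain (pinch anomaly): discard
                loop = []
                break
            prev = cur
            cur = nxts.pop()
            if not nxts:
                del succ[prev]
        if len(loop) >= 3:
            loops.append(np.array(loop, dtype=np.int64))
    return loops


def _interior_reference(grid: SphereGrid, mask: np.ndarray) -> np.ndarray:
    w = grid.areas[mask]
    c = (grid.centroids[mask] * w[:, None]).sum(axis=0)
    n = np.linalg.norm(c)
    if n > 1e-9:
        c = c / n
        if mask[grid.locate(c)]:
            return c
        # centroid fell off the region (non-convex cloud): snap to nearest
        # occupied patch centre
    occ = grid.centroids[mask]
    if n <= 1e-9:
        return occ[0]
    return occ[np.argmax(occ @ c)]


def _select_outer(
    loops: list[np.ndarray], interior: np.ndarray, grid: SphereGrid
) -> SphericalPolygon:
    """Pick the loop that encircles the region (holes wind the other way)."""
    if not loops:
        raise AmbiguousBoundaryError("no boundary loops found")
    best = None
    best_s = 0.0
    for loop in loops:
        poly = SphericalPolygon(grid.vertices[loop], interior)
        s = _signed_fan_area(poly)
        if s > best_s:
            best, best_s = poly, s
    if best is None:
        raise AmbiguousBoundaryError(
            "no loop encloses the occupied region consistently; "
            "the cloud may span more than a hemisphere — use a finer "
            "resolution or a hull method"
        )
    return best


def _signed_fan_area(poly: SphericalPolygon) -> float:
    from .spherical import _spherical_triangle_area

    c = poly.interior_point
    a = poly.vertices
    b = np.roll(a, -1, axis=0)
    return float(np.sum(_spherical_triangle_area(np.broadcast_to(c, a.shape), a, b)))


# ---------------------------------------------------------------------------
# The SFP object
# ---------------------------------------------------------------------------


@dataclass
class SFP:
    """A spherical frame projection: one fitted boundary polygon per frame
    axis, plus the null-pose reference frame (the identity, whose axis
    endpoints are (1,0,0), (0,1,0), (0,0,1))."""

    polygons: dict[str, SphericalPolygon]
    null_pose: Orientation = field(default_factory=Orientation.identity)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [a for a in AXES if a not in self.polygons]
        if missing:
            raise ValidationError(f"SFP requires polygons for X, Y, Z; missing {missing}")

    def areas(self) -> dict[str, float]:
        """Solid angle (steradians) enclosed by each axis polygon."""
        return {a: self.polygons[a].area() for a in AXES}

    def to_dict(self) -> dict:
        return {
            "polygons": {a: self.polygons[a].to_dict() for a in AXES},
            "null_pose": self.null_pose.m.tolist(),
            "metadata": self.metadata,
        }


def build_sfp(
    data: OrientationSet,
    resolution: int = 1280,
    dilation: int = 0,
) -> SFP:
    """Compute the spherical frame projection of an orientation dataset.

    Traces the dataset on the sphere and fits one boundary polygon around
    each of the three axis clouds.  The containment invariant holds by
    construction: every source point lies inside its axis's polygon.
    """
    trace = frame_trace(data)
    grid = default_grid(_level_for(resolution))
    polys = {
        axis: fit_boundary(trace.clouds[axis], dilation=dilation, grid=grid)
        for axis in AXES
    }
    return SFP(
        polys,
        metadata={
            "resolution": grid.n_patches,
            "dilation": dilation,
            "effective_dilation": {
                a: getattr(polys[a], "effective_dilation", dilation) for a in AXES
            },
            "method": "occupancy-grid",
            "n_orientations": len(data),
            "label": data.label,
        },
    )


# ---------------------------------------------------------------------------
# Pose checks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseReport:
    """Per-axis polygon membership of a candidate pose.

    ``all_inside`` is **necessary but not sufficient** for reachability: the
    three axis endpoints could each fall inside its polygon while belonging
    to different real poses, so an all-inside pose may still be infeasible.
    Use :func:`check_pose_path` to additionally require connectivity to a
    known-viable pose.
    """

    inside: dict[str, bool]

    @property
    def all_inside(self) -> bool:
        return all(self.inside.values())


def check_pose(sfp: SFP, o: Orientation) -> PoseReport:
    """Test each frame-axis endpoint of ``o`` against its SFP polygon."""
    return PoseReport(
        {axis: sfp.polygons[axis].contains(o.m[i]) for i, axis in enumerate(AXES)}
    )


@dataclass
class PathResult:
    viable: bool
    path: list[Orientation]


def check_pose_path(
    data: OrientationSet,
    start: Orientation,
    target: Orientation,
    k: int = 6,
    step_max: float = 10.0,
) -> PathResult:
    """Heuristic reachability check through the sampled pose space.

    Builds a graph over the dataset's orientations (plus start and target)
    with an edge wherever the rotational geodesic distance — the angle of the
    relative rotation — is at most ``step_max`` degrees, keeping at most the
    ``k`` nearest such neighbours per node.  The target is deemed viable iff
    it is connected to the start, in which case the connecting pose sequence
    is returned.

    This guards against the membership test's false positives by demanding a
    motion path whose intermediate poses are all sampled; it remains a
    heuristic whose verdict depends on sampling density, ``k`` and
    ``step_max``.

    Raises
    ------
    UnanchoredStartError
        If ``start`` is farther than ``step_max`` from every dataset sample.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    if start.angle_to(target) <= 1e-9:
        return PathResult(True, [start])
    nodes: list[Orientation] = list(data.items) + [start, target]
    quats = np.array([to_quaternion(o).as_array() for o in nodes])
    dots = np.clip(np.abs(quats @ quats.T), -1.0, 1.0)
    dist = 2.0 * np.degrees(np.arccos(dots))
    np.fill_diagonal(dist, np.inf)

    i_start, i_target = len(nodes) - 2, len(nodes) - 1
    if dist[i_start, :-2].min() > step_max:
        raise UnanchoredStartError(
            f"start pose is {dist[i_start, :-2].min():.1f} deg from the nearest "
            f"sample, beyond step_max={step_max} deg"
        )

    n = len(nodes)
    rows, cols, vals = [], [], []
    for i in range(n):
        nbr = np.flatnonzero(dist[i] <= step_max)
        if len(nbr) > k:
            nbr = nbr[np.argsort(dist[i, nbr])[:k]]
        for j in nbr:
            rows.append(i)
            cols.append(int(j))
            vals.append(dist[i, j])
    graph = coo_matrix((vals, (rows, cols)), shape=(n, n))
    d, pred = dijkstra(
        graph, directed=False, indices=i_start, return_predecessors=True
    )
    if not np.isfinite(d[i_target]):
        return PathResult(False, [])
    seq = [i_target]
    while seq[-1] != i_start:
        seq.append(int(pred[seq[-1]]))
    return PathResult(True, [nodes[i] for i in reversed(seq)])


# ---------------------------------------------------------------------------
# Coverage heatmap
# ---------------------------------------------------------------------------

SATURATION_PASSES = 3


@dataclass
class CoverageGrid:
    """Pose-space coverage accumulator on the patch grid.

    Each patch counts *independent passes* of a trace: consecutive samples in
    the same patch count once; re-entering after at least one sample
    elsewhere counts as a new pass.  Display intensity saturates at three
    passes, emulating the live coverage heatmap painted during
    range-of-motion trials.
    """

    grid: SphereGrid
    counts: np.ndarray = None  # type: ignore[assignment]
    _last_patch: int = -1

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.grid.n_patches, dtype=np.int64)

    def intensity(self) -> np.ndarray:
        """Per-patch display intensity in [0, 1]: min(count, 3) / 3."""
        return np.minimum(self.counts, SATURATION_PASSES) / SATURATION_PASSES

    def fraction_visited(self) -> float:
        return float((self.counts > 0).mean())


def coverage_update(grid: CoverageGrid, stream: np.ndarray) -> CoverageGrid:
    """Accumulate a trace-point stream into the coverage grid (in place).

    ``stream`` is an (n, 3) sequence of unit vectors in temporal order; an
    empty stream leaves the grid unchanged.  Streaming state (the patch the
    trace currently dwells in) carries over between calls, so feeding one
    long trace in chunks is equivalent to feeding it at once.
    """
    s = np.atleast_2d(np.asarray(stream, float))
    if s.size == 0:
        return grid
    patches = grid.grid.locate(s)
    last = grid._last_patch
    for p in np.atleast_1d(patches):
        if p != last:
            grid.counts[p] += 1
            last = int(p)
    grid._last_patch = last
    return grid
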