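"""Spherical geometry primitives: geodesic arcs, an icosphere patch grid, and
spherical polygons with area and point-in-polygon tests.

The patch grid is a recursively subdivided icosahedron whose triangular faces
("patches") partition the sphere; patch solid angles sum to 4*pi and are
near-equal in size.  It backs both automated boundary fitting and the
pose-space coverage heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import (
    IndeterminatePathError,
    InvalidPolygonError,
    ValidationError,
)

UNIT_TOL = 1e-9
#: Angular tolerance (radians) under which a query point counts as on an edge;
#: on-edge points are classified inside (closed region).
EDGE_TOL = 1e-9


def _check_unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(n - 1.0) > 1e-6):
        raise ValidationError(f"{name} must be unit length (|norm-1| <= 1e-6)")
    return v


def arc_length(a, b) -> float:
    """Geodesic (great-circle) angle between two unit vectors, in degrees.

    Uses atan2(|a x b|, a . b), which is numerically stable for both nearly
    parallel and nearly antipodal pairs.
    """
    a = _check_unit(a, "a")
    b = _check_unit(b, "b")
    cross = np.cross(a, b)
    return float(np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(a * b, axis=-1))))


def arc_lengths(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Vectorised :func:`arc_length` over arrays broadcastable to (n, 3)."""
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    cross = np.cross(a, b)
    return np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(a * b, axis=-1)))


def geodesic_extent(points: np.ndarray) -> float:
    """Maximal pairwise geodesic distance (degrees) within a point cloud.

    Uses the atan2(|cross|, dot) form so coincident points measure exactly 0
    and nearly-parallel pairs lose no precision.
    """
    p = np.asarray(points, float)
    dots = p @ p.T
    cross = np.cross(p[:, None, :], p[None, :, :])
    sins = np.linalg.norm(cross, axis=-1)
    return float(np.degrees(np.arctan2(sins, dots).max()))


def slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point a fraction ``t`` along the minor arc from ``a`` to ``b``."""
    omega = np.radians(arc_length(a, b))
    if omega < 1e-12:
        return np.asarray(a, float)
    so = np.sin(omega)
    return (np.sin((1 - t) * omega) * np.asarray(a) + np.sin(t * omega) * np.asarray(b)) / so


# ---------------------------------------------------------------------------
# Icosphere patch grid
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Vertices and CCW-from-outside faces of a unit icosahedron."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    # orient all faces CCW viewed from outside (outward normal)
    for i, (a, b, c) in enumerate(faces):
        if np.linalg.det(verts[[a, b, c]]) < 0:
            faces[i] = [a, c, b]
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-way triangular subdivision, midpoints projected to the sphere."""
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def _spherical_triangle_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Signed solid angle of spherical triangle(s) via Van Oosterom-Strackee."""
    num = np.sum(a * np.cross(b, c), axis=-1)
    den = 1.0 + np.sum(a * b, axis=-1) + np.sum(b * c, axis=-1) + np.sum(a * c, axis=-1)
    return 2.0 * np.arctan2(num, den)


class SphereGrid:
    """Subdivided-icosahedron partition of the sphere into triangular patches.

    Parameters
    ----------
    subdivisions:
        Number of 4-way subdivisions; patch count is ``20 * 4**subdivisions``
        (3 subdivisions -> 1280 patches, the default boundary-fitting
        resolution).
    """

    def __init__(self, subdivisions: int = 3):
        if subdivisions < 0 or subdivisions > 7:
            raise ValueError("subdivisions must be in [0, 7]")
        self.subdivisions = subdivisions
        verts, faces = _icosahedron()
        for _ in range(subdivisions):
            verts, faces = _subdivide(verts, faces)
        self.vertices = verts
        self.faces = faces
        self.centroids = self._face_centroids()
        # inward edge-plane normals for exact point-in-patch tests:
        # normal[f, e] = v[e] x v[(e+1)%3], positive dot => inside that edge
        tri = verts[faces]  # (F, 3, 3)
        self._edge_normals = np.cross(tri, np.roll(tri, -1, axis=1))
        self.areas = np.abs(
            _spherical_triangle_area(tri[:, 0], tri[:, 1], tri[:, 2])
        )
        self._adjacency = self._build_adjacency()

    @property
    def n_patches(self) -> int:
        return len(self.faces)

    @classmethod
    def from_patch_count(cls, n_patches: int) -> "SphereGrid":
        """Grid with at least ``n_patches`` patches (rounded up to a level)."""
        for s in range(8):
            if 20 * 4**s >= n_patches:
                return cls(s)
        raise ValueError("requested patch count too large")

    def _face_centroids(self) -> np.ndarray:
        c = self.vertices[self.faces].mean(axis=1)
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    def _build_adjacency(self) -> np.ndarray:
        """(F, 3) neighbour face index across each edge."""
        edge_to_face: dict[tuple[int, int], list[int]] = {}
        for f, (a, b, c) in enumerate(self.faces):
            for i, j in ((a, b), (b, c), (c, a)):
                edge_to_face.setdefault((min(i, j), max(i, j)), []).append(f)
        adj = np.full((len(self.faces), 3), -1, dtype=np.int64)
        for f, (a, b, c) in enumerate(self.faces):
            for e, (i, j) in enumerate(((a, b), (b, c), (c, a))):
                pair = edge_to_face[(min(i, j), max(i, j))]
                adj[f, e] = pair[0] if pair[1] == f else pair[1]
        return adj

    @property
    def adjacency(self) -> np.ndarray:
        return self._adjacency

    def max_patch_width(self) -> float:
        """Maximal patch extent: the longest edge arc over all patches, deg."""
        tri = self.vertices[self.faces]
        e = arc_lengths(tri.reshape(-1, 3), np.roll(tri, -1, axis=1).reshape(-1, 3))
        return float(e.max())

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Patch index of each point (exact spherical-triangle containment,
        nearest-centroid fallback for points numerically on patch edges)."""
        p = np.atleast_2d(np.asarray(points, float))
        # seed with nearest centroid, verify, and fix stragglers exactly
        idx = np.argmax(p @ self.centroids.T, axis=1)
        inside = np.all(
            np.einsum("nej,nj->ne", self._edge_normals[idx], p) >= -1e-12, axis=1
        )
        bad = np.flatnonzero(~inside)
        if len(bad):
            # exhaustive exact test for the few near-edge/misfiled points
            sides = np.einsum("fej,nj->nfe", self._edge_normals, p[bad])
            ok = np.all(sides >= -1e-12, axis=2)  # (nbad, F)
            for k, row in enumerate(ok):
                cand = np.flatnonzero(row)
                if len(cand):
                    idx[bad[k]] = cand[np.argmax(p[bad[k]] @ self.centroids[cand].T)]
        if np.asarray(points).ndim == 1:
            return int(idx[0])
        return idx

    def dilate(self, mask: np.ndarray, rings: int) -> np.ndarray:
        """Grow an occupied-patch mask by ``rings`` layers of edge-neighbours."""
        out = mask.copy()
        for _ in range(rings):
            grown = out.copy()
            grown[self._adjacency[out].ravel()] = True
            out = grown
        return out

    def connected_components(self, mask: np.ndarray) -> list[np.ndarray]:
        """Edge-connected components of an occupied-patch mask, largest first."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components as _cc

        occ = np.flatnonzero(mask)
        if len(occ) == 0:
            return []
        pos = {f: i for i, f in enumerate(occ)}
        rows, cols = [], []
        for i, f in enumerate(occ):
            for nb in self._adjacency[f]:
                if mask[nb]:
                    rows.append(i)
                    cols.append(pos[nb])
        graph = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(occ), len(occ))
        )
        n, labels = _cc(graph, directed=False)
        comps = [occ[labels == k] for k in range(n)]
        comps.sort(key=len, reverse=True)
        return comps


@lru_cache(maxsize=8)
def default_grid(subdivisions: int = 3) -> SphereGrid:
    """Shared, cached grid instance (construction is the expensive part)."""
    return SphereGrid(subdivisions)


# ---------------------------------------------------------------------------
# Spherical polygons
# ---------------------------------------------------------------------------


@dataclass
class SphericalPolygon:
    """A closed spherical polygon: ordered vertex loop joined by minor
    great-circle arcs, plus an explicit interior reference point that selects
    which side of the loop is "inside".

    Vertices are stored counter-clockwise as seen from outside the sphere
    (looking down at the interior reference point).
    """

    vertices: np.ndarray
    interior_point: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 3:
            raise InvalidPolygonError("polygon needs >= 3 vertices of shape (n, 3)")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidPolygonError("polygon vertices must be unit vectors")
        self.vertices = v / norms[:, None]
        nxt = np.roll(self.vertices, -1, axis=0)
        if np.any(np.sum(self.vertices * nxt, axis=1) < -1 + 1e-12):
            raise InvalidPolygonError("consecutive vertices must not be antipodal")
        self.interior_point = np.asarray(self.interior_point, float)
        self.interior_point /= np.linalg.norm(self.interior_point)

    def __len__(self) -> int:
        return len(self.vertices)

    # -- area --------------------------------------------------------------

    def area(self) -> float:
        """Enclosed solid angle in steradians, on the interior-point side.

        Computed as the sum of signed spherical-triangle excesses of the fan
        from the interior reference point (equivalent to the spherical-excess
        formula sum(interior angles) - (n-2)*pi).  Result is in (0, 4*pi).
        """
        c = self.interior_point
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        s = float(np.sum(_spherical_triangle_area(np.broadcast_to(c, a.shape), a, b)))
        # the loop winds once around the interior point; the fan sum's
        # magnitude is the enclosed solid angle on that side, its sign only
        # the storage orientation
        return abs(s)

    def validate_simple(self) -> None:
        """Raise :class:`InvalidPolygonError` if any two non-adjacent edges
        cross (self-intersecting loop)."""
        n = len(self.vertices)
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or (j - i) % n == 1 or (i - j) % n == 1:
                    continue
                if _arcs_cross(a[i], b[i], a[j], b[j]):
                    raise InvalidPolygonError(
                        f"edges {i} and {j} intersect: polygon is not simple"
                    )

    # -- containment -------------------------------------------------------

    def contains(self, point, *, edge_tol: float = EDGE_TOL) -> bool:
        """True iff ``point`` lies on the interior side of the boundary.

        Counts great-circle edge crossings along the geodesic from the
        interior reference point to the query; an even count means the query
        shares the reference point's side.  Points within ``edge_tol``
        (radians) of an edge are classified inside (closed region), which
        keeps every boundary-defining sample inside its fitted polygon.
        """
        q = _check_unit(point, "query point")
        if float(np.dot(q, self.interior_point)) < -1 + 1e-12:
            raise IndeterminatePathError(
                "query is antipodal to the interior reference point; "
                "retry with a jittered reference"
            )
        # fast accept: on an edge
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        if np.any(_point_edge_distance(q, a, b) <= edge_tol):
            return True
        crossings = 0
        r = self.interior_point
        for tries in range(6):
            crossings = 0
            degenerate = False
            for i in range(len(a)):
                x = _arc_crossing(r, q, a[i], b[i])
                if x is None:
                    degenerate = True
                    break
                crossings += x
            if not degenerate:
                break
            # geodesic grazes a vertex: deterministically jitter the reference
            # (well past the graze-detection window, far below patch scale)
            r = _jitter(self.interior_point, 1e-5 * (tries + 1) ** 2)
        else:  # pragma: no cover - pathological
            raise IndeterminatePathError("containment ray degenerate after jitter")
        return crossings % 2 == 0

    def contains_many(self, points: np.ndarray, **kw) -> np.ndarray:
        return np.array([self.contains(p, **kw) for p in np.atleast_2d(points)])

    def to_dict(self) -> dict:
        return {
            "vertices": self.vertices.tolist(),
            "interior_point": self.interior_point.tolist(),
            "area_sr": self.area(),
        }


def _jitter(v: np.ndarray, eps: float) -> np.ndarray:
    # deterministic tangent-direction jitter
    t = np.cross(v, [1.0, 0.61803398875, 0.3819660112])
    n = np.linalg.norm(t)
    if n < 1e-9:
        t = np.cross(v, [0.0, 1.0, 0.0])
        n = np.linalg.norm(t)
    out = v + eps * t / n
    return out / np.linalg.norm(out)


def _within_arc(x: np.ndarray, a: np.ndarray, b: np.ndarray, n: np.ndarray) -> bool:
    """Is great-circle point x within the minor arc a->b (n = a x b)?"""
    return bool(np.dot(np.cross(a, x), n) >= -1e-15 and np.dot(np.cross(x, b), n) >= -1e-15)


def _arc_crossing(p: np.ndarray, q: np.ndarray, a: np.ndarray, b: np.ndarray):
    """0/1 crossing count of minor arcs p->q and a->b; None if degenerate
    (an endpoint lies exactly on the other arc's great circle intersection)."""
    n1 = np.cross(p, q)
    n2 = np.cross(a, b)
    t = np.cross(n1, n2)
    nt = np.linalg.norm(t)
    if nt < 1e-12:  # same great circle
        return None
    t /= nt
    count = 0
    for x in (t, -t):
        on1 = _within_arc(x, p, q, n1)
        on2 = _within_arc(x, a, b, n2)
        if on1 and on2:
            # graze at any endpoint (ray's or edge's) => degenerate: the
            # crossing parity is ill-defined, ask the caller to jitter.
            # |x cross e| measures the angular separation directly, so the
            # window (1e-12 rad) stays far below the jitter scale
            for e in (p, q, a, b):
                if np.linalg.norm(np.cross(x, e)) < 1e-12:
                    return None
            count += 1
    return count


def _arcs_cross(a1, b1, a2, b2) -> bool:
    """Strict interior crossing of two minor arcs (shared endpoints ignored)."""
    n1 = np.cross(a1, b1)
    n2 = np.cross(a2, b2)
    t = np.cross(n1, n2)
    nt = np.linalg.norm(t)
    if nt < 1e-12:
        return False
    t /= nt
    for x in (t, -t):
        if _within_arc(x, a1, b1, n1) and _within_arc(x, a2, b2, n2):
            ends = np.array([a1, b1, a2, b2])
            if np.all(np.abs(ends @ x) < 1 - 1e-12):
                return True
    return False


def _point_edge_distance(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angular distance (radians) from q to each minor arc a[i]->b[i]."""
    n = np.cross(a, b)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nn[nn == 0] = 1.0
    nu = n / nn
    # distance to the full great circle
    d_gc = np.abs(np.arcsin(np.clip(nu @ q, -1.0, 1.0)))
    # foot of perpendicular within the arc?
    foot = q - (nu @ q)[:, None] * nu
    fn = np.linalg.norm(foot, axis=1, keepdims=True)
    fn[fn == 0] = 1.0
    foot = foot / fn
    within = np.array([_within_arc(foot[i], a[i], b[i], n[i]) for i in range(len(a))])
    d_ends = np.minimum(
        np.arccos(np.clip(a @ q, -1, 1)), np.arccos(np.clip(b @ q, -1, 1))
    )
    return np.where(within, d_gc, d_ends)
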