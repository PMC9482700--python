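"""Marker-to-joint rigid transform chain.

A range-of-motion rig tracks a marker tree rigidly attached to the distal
bone while the proximal bone is fixed to a base.  Converting tracked marker
poses into joint-centric orientations is a chain of 4x4 homogeneous
transforms between the frames involved: base, mounting plates, bones
(anatomical coordinate systems, ACS) and markers.

Notation: ``T_AB`` (written ``^A T_B`` in chain form) maps coordinates
expressed in frame B into frame A.  The joint orientation delivered to the
spherical frame projection is the rotation block of ``T`` from proximal ACS
to distal ACS, whose rows are the distal axis endpoints in the proximal
frame.

The module also fits the plate and bone frames from labelled landmark points
(least-squares planes and lines) and exactly orthogonalises near-orthogonal
axis triads by the recursive cross-product averaging scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FitError, ValidationError
from .orientations import ORTHONORMALITY_TOL, Orientation, validate as _validate_rot

#: Convergence tolerance for exact orthogonalisation (max pairwise |dot|).
ORTHOGONALISE_TOL = 1e-12


class RigidTransform:
    """A 4x4 homogeneous rigid transform: rotation block R and translation t
    (mm by convention throughout rig files)."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray, *, _skip_validation: bool = False):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not _skip_validation:
            if np.abs(m[3] - np.array([0, 0, 0, 1.0])).max() > ORTHONORMALITY_TOL:
                raise ValidationError("bottom row must be (0, 0, 0, 1)")
            rep = _validate_rot(m[:3, :3])
            if not rep.ok:
                raise ValidationError(
                    "rotation block is not a proper rotation "
                    f"(residual {rep.orthonormality_residual:.3e}, det {rep.determinant:.9f})"
                )
        self.matrix = m

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4), _skip_validation=True)

    @classmethod
    def from_rt(cls, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra -----------------------------------------------------------

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix, _skip_validation=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (n, 3) or (3,) points."""
        p = np.asarray(points, float)
        return p @ self.rotation.T + self.translation

    def orientation(self) -> Orientation:
        """The rotational component as an :class:`Orientation`; translation is
        discarded.

        For a transform ``^A T_B`` (maps B-frame coordinates into frame A) the
        rows of the rotation block are frame A's axes expressed in frame B, so
        ``dACS_T_pACS.orientation()`` directly yields the distal axis endpoints
        in the proximal frame — the points the SFP plots.
        """
        return Orientation(self.rotation)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RigidTransform({np.array_repr(self.matrix)})"


def invert(T: RigidTransform) -> RigidTransform:
    """Exact rigid inverse: rotation transposed, translation -R^T t.

    For a pure rotation (zero translation) this coincides with the 4x4
    transpose; with nonzero translation only the rotation block transposes —
    the translation must be rotated back as well.  ``T @ invert(T)`` is the
    identity to machine precision.
    """
    R = T.rotation
    m = np.eye(4)
    m[:3, :3] = R.T
    m[:3, 3] = -R.T @ T.translation
    return RigidTransform(m, _skip_validation=True)


def joint_orientation(
    markers_T_base: RigidTransform,
    pACS_T_pPlate: RigidTransform,
    pPlate_T_base: RigidTransform,
    dACS_T_dPlate: RigidTransform,
    dPlate_T_markers: RigidTransform,
) -> Orientation:
    """Resolve the joint orientation (distal ACS in proximal ACS) from the
    tracked marker pose and the four rig/specimen transforms.

    The chain is::

        pACS_T_base   = pACS_T_pPlate @ pPlate_T_base
        dACS_T_markers = dACS_T_dPlate @ dPlate_T_markers
        dACS_T_pACS   = dACS_T_markers @ markers_T_base @ invert(pACS_T_base)

    Only the rotational component is returned.  Because the rotation block of
    a product of rigid transforms is the product of the rotation blocks, the
    result is invariant to the translation of every transform in the chain.
    """
    for name, T in (
        ("markers_T_base", markers_T_base),
        ("pACS_T_pPlate", pACS_T_pPlate),
        ("pPlate_T_base", pPlate_T_base),
        ("dACS_T_dPlate", dACS_T_dPlate),
        ("dPlate_T_markers", dPlate_T_markers),
    ):
        if not isinstance(T, RigidTransform):
            raise ValidationError(f"{name} must be a RigidTransform")
    pACS_T_base = pACS_T_pPlate @ pPlate_T_base
    dACS_T_markers = dACS_T_dPlate @ dPlate_T_markers
    dACS_T_pACS = dACS_T_markers @ markers_T_base @ invert(pACS_T_base)
    return dACS_T_pACS.orientation()


# ---------------------------------------------------------------------------
# Landmark-based frame fitting
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Labelled 3D points (mm) grouped by geometric feature.

    ``groups`` maps a feature name (e.g. ``"face_x"``, ``"proximal_edge"``)
    to an (n, 3) array.  Plane fits need >= 3 non-collinear points; line fits
    need >= 2 points.  Edge point groups are ordered along the edge; the
    first-to-last direction fixes the fitted line's sign.
    """

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.atleast_2d(np.asarray(v, float)) for k, v in self.groups.items()}
        for k, v in self.groups.items():
            if v.shape[1] != 3:
                raise ValidationError(f"group {k!r} must be (n, 3) points")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.groups[key]


@dataclass(frozen=True)
class FrameFit:
    """A fitted frame with its fit residuals."""

    transform: RigidTransform
    max_point_residual: float  # mm, point-to-plane or point-to-line
    max_axis_dot: float  # after orthogonalisation; <= 1e-12


def _fit_plane(points: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane: returns (centroid, unit normal, max |distance|)."""
    if len(points) < 3:
        raise FitError(f"plane fit for {name!r} needs >= 3 points")
    c = points.mean(axis=0)
    d = points - c
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise FitError(f"points in {name!r} are collinear; cannot fit a plane")
    n = vt[2]
    return c, n, float(np.abs(d @ n).max())


def _fit_line(points: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal-direction line: returns (centroid, unit direction, max residual).

    Direction sign follows the first-to-last point ordering.
    """
    if len(points) < 2:
        raise FitError(f"line fit for {name!r} needs >= 2 points")
    c = points.mean(axis=0)
    d = points - c
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[0] < 1e-12:
        raise FitError(f"points in {name!r} are coincident; cannot fit a line")
    u = vt[0]
    span = points[-1] - points[0]
    if np.dot(u, span) < 0:
        u = -u
    resid = float(np.linalg.norm(d - np.outer(d @ u, u), axis=1).max()) if len(points) > 2 else 0.0
    return c, u, resid


def fit_plate_frame(points: LandmarkSet) -> FrameFit:
    """Fit a mounting plate's local frame from points placed on its faces.

    The landmark set must provide groups ``face_x``, ``face_y`` and
    ``face_z``: points on the three mutually perpendicular faces whose
    outward normals define the X, Y and Z axes.  Each face is fitted with a
    least-squares plane; normals are signed outward (away from the landmark
    centroid), exactly orthogonalised, and the origin is placed at the
    corner where the three fitted planes intersect.  Using many points per
    face filters placement and digitisation noise.
    """
    required = ("face_x", "face_y", "face_z")
    missing = [g for g in required if g not in points.groups]
    if missing:
        raise FitError(f"plate landmarks missing face groups: {missing}")
    body_centroid = np.concatenate([points[g] for g in required]).mean(axis=0)
    normals, centroids, resid = [], [], 0.0
    for g in required:
        c, n, r = _fit_plane(points[g], g)
        if np.dot(n, c - body_centroid) < 0:  # outward
            n = -n
        normals.append(n)
        centroids.append(c)
        resid = max(resid, r)
    axes = orthogonalise(np.array(normals))
    # origin: intersection of the three planes (n_i . x = n_i . c_i)
    A = np.array(normals)
    b = np.array([np.dot(n, c) for n, c in zip(normals, centroids)])
    origin = np.linalg.solve(A, b)
    R = axes.T  # columns = axes expressed in scan frame: maps plate->scan
    T = RigidTransform.from_rt(R, origin)
    return FrameFit(T, resid, _max_pairwise_dot(axes))


def fit_bone_frame(proximal_pts: LandmarkSet | np.ndarray, distal_pts: LandmarkSet | np.ndarray) -> FrameFit:
    """Fit a bone's anatomical frame from points along its proximal and
    distal articular edges.

    Lines are fitted through each edge point set; the long axis (X) runs
    from the proximal edge-line midpoint to the distal midpoint, the second
    axis (Z) follows the proximal edge-line direction, and Y completes the
    right-handed triad.  The triad is exactly orthogonalised and the origin
    sits at the proximal midpoint.  Which anatomical motion each axis
    represents is a labelling convention left to the caller's configuration.
    """
    prox = proximal_pts["edge"] if isinstance(proximal_pts, LandmarkSet) else np.atleast_2d(proximal_pts)
    dist = distal_pts["edge"] if isinstance(distal_pts, LandmarkSet) else np.atleast_2d(distal_pts)
    c_p, u_p, r_p = _fit_line(np.asarray(prox, float), "proximal edge")
    c_d, u_d, r_d = _fit_line(np.asarray(dist, float), "distal edge")
    long_axis = c_d - c_p
    n = np.linalg.norm(long_axis)
    if n < 1e-9:
        raise FitError("proximal and distal edge midpoints coincide; long axis undefined")
    x = long_axis / n
    z = u_p - np.dot(u_p, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise FitError("edge line is parallel to the long axis; frame undefined")
    z /= nz
    y = np.cross(z, x)
    axes = orthogonalise(np.array([x, y, z]))
    T = RigidTransform.from_rt(axes.T, c_p)
    return FrameFit(T, max(r_p, r_d), _max_pairwise_dot(axes))


def _ortho_step(a: np.ndarray, i: int) -> None:
    """One averaging step in place: pull axis ``i`` toward the (sign-matched)
    cross product of the other two."""
    j, k = (i + 1) % 3, (i + 2) % 3
    c = np.cross(a[j], a[k])
    if np.dot(c, a[i]) < 0:
        c = -c
    c /= np.linalg.norm(c)
    new = a[i] + c
    a[i] = new / np.linalg.norm(new)


def _max_pairwise_dot(axes: np.ndarray) -> float:
    return float(
        max(
            abs(np.dot(axes[0], axes[1])),
            abs(np.dot(axes[1], axes[2])),
            abs(np.dot(axes[0], axes[2])),
        )
    )


def orthogonalise(
    axes: np.ndarray,
    tol: float = ORTHOGONALISE_TOL,
    max_iter: int = 10_000,
    fix_handedness: bool = True,
) -> np.ndarray:
    """Exactly orthogonalise three near-orthogonal unit axes.

    Recursive cross-product averaging: cycling through the axes, each axis is
    replaced by the normalised average of itself and the cross product of the
    other two (sign-matched so the correction attracts rather than flips),
    nudging the triad marginally in turn until every pairwise dot product is
    zero to within ``tol``.  The residual decreases monotonically and the
    scheme converges quadratically near orthogonality.

    Parameters
    ----------
    axes:
        (3, 3) array, rows = axis vectors; pairwise |dot| must be < 0.5 so
        the rows are recognisably a frame.
    fix_handedness:
        Left-handed input is corrected by flipping the third axis when True,
        rejected with :class:`FitError` when False.

    Returns
    -------
    (3, 3) array of exactly orthonormal, right-handed rows.
    """
    a = np.asarray(axes, dtype=float).copy()
    if a.shape != (3, 3):
        raise ValidationError("expected three 3-vectors (shape (3, 3))")
    norms = np.linalg.norm(a, axis=1)
    if np.any(norms < 1e-9):
        raise ValidationError("axes must be nonzero")
    a /= norms[:, None]
    if _max_pairwise_dot(a) >= 0.5:
        raise FitError("axes are not recognisably a frame (some |dot| >= 0.5)")
    if np.linalg.det(a) < 0:
        if not fix_handedness:
            raise FitError("left-handed axis triad rejected (fix_handedness=False)")
        a[2] = -a[2]
    for it in range(max_iter):
        if _max_pairwise_dot(a) <= tol:
            break
        _ortho_step(a, it % 3)
    else:
        raise FitError(
            f"orthogonalisation did not converge: residual {_max_pairwise_dot(a):.3e}"
        )
    return a
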