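"""Rotation representations for joint pose data.

A joint pose is the orientation of the distal bone's anatomical coordinate
system (ACS) relative to the proximal bone's ACS.  Throughout this package an
:class:`Orientation` stores the 3x3 matrix whose *rows* are the endpoints of
the distal frame's X, Y and Z axes expressed in the proximal frame — this is
the matrix whose rows are plotted directly on the unit sphere by the spherical
frame projection.  The conventional "active" rotation matrix (columns = rotated
axes; the matrix that maps distal-frame vector coordinates into the proximal
frame is its transpose) is available as :attr:`Orientation.rotation`.

Angles are degrees at every public interface and radians only internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _R

from .exceptions import InvalidSequenceError, UndefinedAxisError, ValidationError

#: Orthonormality / determinant tolerance.  Double-precision composition of a
#: chain of ten rotations accumulates error well below this.
ORTHONORMALITY_TOL = 1e-9

_AXES = {"X", "Y", "Z"}


@dataclass(frozen=True)
class EulerSpec:
    """An Euler angle triplet with a declared axis sequence and convention.

    Parameters
    ----------
    sequence:
        Ordered axis labels, e.g. ``"ZYX"``.  Consecutive labels must differ.
    angles:
        Three rotation angles in **degrees**, one per axis in ``sequence``.
    intrinsic:
        If True (default) the rotations compose about the moving (body) axes;
        otherwise about the fixed (space) axes.  The default follows the common
        biomechanical assignment of Z as the flexion/extension axis applied
        first, i.e. intrinsic Z-Y-X, but any sequence may be declared.
    """

    sequence: str = "ZYX"
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intrinsic: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != 3 or any(a not in _AXES for a in seq):
            raise InvalidSequenceError(
                f"sequence must be three labels from X/Y/Z, got {self.sequence!r}"
            )
        if seq[0] == seq[1] or seq[1] == seq[2]:
            raise InvalidSequenceError(
                f"consecutive axis labels must differ: {self.sequence!r}"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))

    @property
    def scipy_seq(self) -> str:
        """Sequence string in scipy convention (upper = intrinsic)."""
        return self.sequence if self.intrinsic else self.sequence.lower()


@dataclass(frozen=True)
class UnitQuaternion:
    """A unit quaternion (w, x, y, z), canonicalised to the w >= 0 hemisphere.

    When w == 0 the first nonzero vector component is made positive, so every
    rotation has a unique representative.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        q = np.array([self.w, self.x, self.y, self.z], dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > ORTHONORMALITY_TOL:
            raise ValidationError(f"quaternion norm {n} differs from 1 beyond tolerance")
        q = _canonical(q)
        object.__setattr__(self, "w", float(q[0]))
        object.__setattr__(self, "x", float(q[1]))
        object.__setattr__(self, "y", float(q[2]))
        object.__setattr__(self, "z", float(q[3]))

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def vector(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _canonical(q: np.ndarray) -> np.ndarray:
    """Map a (w, x, y, z) quaternion to the canonical hemisphere."""
    if q[0] < 0:
        return -q
    if q[0] == 0:
        for c in q[1:]:
            if c != 0:
                return q if c > 0 else -q
    return q


class Orientation:
    """A proper rotation stored as the row-endpoint matrix.

    ``m[0]``, ``m[1]``, ``m[2]`` are the unit endpoints of the distal frame's
    X, Y, Z axes in proximal-frame coordinates.
    """

    __slots__ = ("m",)

    def __init__(self, m: np.ndarray, *, _skip_validation: bool = False):
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"expected a 3x3 matrix, got shape {m.shape}")
        if not _skip_validation:
            rep = validate(m)
            if not rep.ok:
                raise ValidationError(
                    "matrix is not a proper rotation: "
                    f"orthonormality residual {rep.orthonormality_residual:.3e}, "
                    f"determinant {rep.determinant:.12f}"
                )
        self.m = m

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3), _skip_validation=True)

    @classmethod
    def from_rotation(cls, rotation: np.ndarray) -> "Orientation":
        """Build from a conventional column-axes rotation matrix."""
        return cls(np.asarray(rotation, dtype=float).T)

    @property
    def rotation(self) -> np.ndarray:
        """The conventional rotation matrix (columns = distal axes in the
        proximal frame); equals ``m.T``."""
        return self.m.T

    # -- algebra -----------------------------------------------------------

    def compose(self, other: "Orientation") -> "Orientation":
        """Apply ``other``'s rotation after this one (left-multiplication of
        the conventional rotation matrices)."""
        return Orientation.from_rotation(other.rotation @ self.rotation)

    def inverse(self) -> "Orientation":
        return Orientation(self.m.T, _skip_validation=True)

    def angle_to(self, other: "Orientation") -> float:
        """Geodesic rotation distance in degrees: the angle of the relative
        rotation taking this orientation to ``other``."""
        rel = self.rotation.T @ other.rotation
        c = (np.trace(rel) - 1.0) / 2.0
        v = 0.5 * np.array(
            [rel[2, 1] - rel[1, 2], rel[0, 2] - rel[2, 0], rel[1, 0] - rel[0, 1]]
        )
        # atan2 form: full precision for small angles, stable near 180
        return float(np.degrees(np.arctan2(np.linalg.norm(v), c)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Orientation({np.array_repr(self.m)})"


@dataclass
class OrientationSet:
    """An ordered range-of-motion dataset of orientations.

    All downstream operations (frame traces, boundary fitting) require a
    non-empty set; construction enforces it.
    """

    items: list[Orientation]
    timestamps: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.items = list(self.items)
        if not self.items:
            raise ValidationError("OrientationSet must be non-empty")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != len(self.items):
                raise ValidationError("timestamps length must match items length")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Orientation]:
        return iter(self.items)

    def __getitem__(self, i: int) -> Orientation:
        return self.items[i]

    def matrices(self) -> np.ndarray:
        """Stacked row-endpoint matrices, shape (n, 3, 3)."""
        return np.stack([o.m for o in self.items])

    def subset(self, indices: Sequence[int], label: str | None = None) -> "OrientationSet":
        ts = self.timestamps[list(indices)] if self.timestamps is not None else None
        return OrientationSet(
            [self.items[i] for i in indices], ts, label if label is not None else self.label
        )


@dataclass(frozen=True)
class ValidationReport:
    """Numerical validity report for a candidate rotation matrix."""

    orthonormality_residual: float
    determinant: float
    tol: float = ORTHONORMALITY_TOL

    @property
    def ok(self) -> bool:
        return (
            self.orthonormality_residual <= self.tol
            and abs(self.determinant - 1.0) <= self.tol
        )


def validate(m: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> ValidationReport:
    """Report how far ``m`` is from a proper rotation.

    The orthonormality residual is ``max |m m^T - I|``; the determinant is
    reported as-is so reflections (det = -1) fail explicitly.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 matrix, got shape {m.shape}")
    residual = float(np.abs(m @ m.T - np.eye(3)).max())
    det = float(np.linalg.det(m))
    return ValidationReport(residual, det, tol)


def from_euler(spec: EulerSpec) -> Orientation:
    """Compose the single-axis rotations declared by ``spec`` into an
    :class:`Orientation`.

    The composed conventional rotation applies the first listed axis rotation
    first; the stored matrix is its transpose (rows = axis endpoints).
    """
    rot = _R.from_euler(spec.scipy_seq, spec.angles, degrees=True)
    return Orientation.from_rotation(rot.as_matrix())


def to_quaternion(o: Orientation) -> UnitQuaternion:
    """Unit quaternion of the joint rotation, canonical hemisphere.

    The quaternion represents the conventional rotation
    :attr:`Orientation.rotation`, so a +30 deg flexion about Z maps to a
    quaternion with axis (0, 0, 1).
    """
    q = _R.from_matrix(o.rotation).as_quat()  # scipy order (x, y, z, w)
    return UnitQuaternion(q[3], q[0], q[1], q[2])


def from_quaternion(q: UnitQuaternion) -> Orientation:
    rot = _R.from_quat([q.x, q.y, q.z, q.w]).as_matrix()
    return Orientation.from_rotation(rot)


def rotation_axis(o: Orientation, tol_deg: float = 1e-9) -> tuple[np.ndarray, float]:
    """Axis-angle decomposition of the joint rotation.

    Returns a unit axis (the canonical quaternion's vector part, normalised)
    and the rotation angle in degrees, in (0, 180].  A rotation of -30 deg
    about Z is reported as 30 deg about (0, 0, -1): the axis carries the sign,
    the angle is always positive.

    Raises
    ------
    UndefinedAxisError
        If the rotation angle is below ``tol_deg`` (identity: no axis).
    """
    q = to_quaternion(o)
    angle = 2.0 * np.degrees(np.arctan2(np.linalg.norm(q.vector()), q.w))
    if angle <= tol_deg:
        raise UndefinedAxisError("identity rotation has no defined axis")
    v = q.vector()
    return v / np.linalg.norm(v), float(angle)


def axis_angle(axis: Iterable[float], angle_deg: float) -> Orientation:
    """Orientation for a rotation of ``angle_deg`` about ``axis``."""
    a = np.asarray(list(axis), dtype=float)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise ValidationError("rotation axis must be nonzero")
    rot = _R.from_rotvec(a / n * np.radians(angle_deg))
    return Orientation.from_rotation(rot.as_matrix())
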