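"""Ground-truth synthetic range-of-motion data and virtual rig sessions.

Two generators make the whole pipeline testable without any captured data:

* :func:`generate_rom` produces orientation datasets for canonical joint
  regimes — a single degree of freedom (DoF), independent 2-DoF and 3-DoF
  Euler boxes, and coupled DoF where the allowed range of one axis depends on
  the position of another.
* :func:`simulate_session` emulates a capture session on the physical rig:
  for each ground-truth joint pose it forward-composes the marker-to-joint
  transform chain to place a rigid marker tree in the base frame, adds
  isotropic Gaussian marker noise, and evaluates a passive-torque model.

The torque model is a piecewise power-law spring: zero inside a soft-limit
onset angle, ``stiffness * excess**exponent`` beyond it (per axis), a simple
nonlinear stand-in for soft-tissue stress-strain behaviour.  All outputs are
deterministic for a given spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .orientations import EulerSpec, Orientation, OrientationSet, from_euler
from .transforms import RigidTransform, invert

# ---------------------------------------------------------------------------
# RoM specification and sampling
# ---------------------------------------------------------------------------

MODES = ("one_dof", "two_dof", "three_dof_box", "coupled")


@dataclass(frozen=True)
class CouplingRule:
    """Piecewise-linear limit of one axis as a function of another.

    ``table`` lists (driving angle, half range) pairs in degrees; the
    dependent axis's half-range at any driving angle is linearly
    interpolated (clamped at the table ends).
    """

    driving: int  # index into the Euler sequence
    dependent: int
    table: tuple[tuple[float, float], ...]

    def half_range(self, driving_angle) -> np.ndarray:
        xs = np.array([p[0] for p in self.table], float)
        ys = np.array([p[1] for p in self.table], float)
        order = np.argsort(xs)
        return np.interp(driving_angle, xs[order], ys[order])


@dataclass(frozen=True)
class RomSpec:
    """Generative description of a synthetic joint's reachable rotation set.

    Parameters
    ----------
    mode:
        ``one_dof`` | ``two_dof`` | ``three_dof_box`` | ``coupled``.
    half_ranges:
        Per-axis half-ranges in degrees, in ``sequence`` order.  Axes beyond
        the mode's DoF count are held at zero.
    sequence, intrinsic:
        Euler sequence the angles compose in (default intrinsic X-Y-Z for the
        1/2-DoF demonstration regimes; any sequence may be declared).
    sampling:
        ``grid`` (regular, ``grid_step`` degrees per axis) or ``random``
        (uniform over the box, ``n_samples`` draws).
    coupling:
        Required in ``coupled`` mode: samples violating the interpolated
        limit of the dependent axis are rejected.
    """

    mode: str = "two_dof"
    half_ranges: tuple[float, float, float] = (30.0, 15.0, 0.0)
    sequence: str = "XYZ"
    intrinsic: bool = True
    sampling: str = "grid"
    grid_step: float = 5.0
    n_samples: int = 500
    coupling: CouplingRule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if any(h < 0 for h in self.half_ranges):
            raise ValidationError("half-ranges must be >= 0")
        if self.sampling == "grid" and self.grid_step <= 0:
            raise ValidationError("grid step must be > 0")
        if self.mode == "coupled" and self.coupling is None:
            raise ValidationError("coupled mode requires a CouplingRule")

    def effective_half_ranges(self) -> tuple[float, float, float]:
        ndof = {"one_dof": 1, "two_dof": 2, "three_dof_box": 3, "coupled": 3}[self.mode]
        return tuple(h if i < ndof else 0.0 for i, h in enumerate(self.half_ranges))


def sample_angles(spec: RomSpec) -> np.ndarray:
    """Sample (n, 3) Euler angle tuples (degrees) from the spec's regime."""
    hr = spec.effective_half_ranges()
    if spec.sampling == "grid":
        axes_vals = [
            np.arange(-h, h + spec.grid_step / 2, spec.grid_step) if h > 0 else np.array([0.0])
            for h in hr
        ]
        grids = np.meshgrid(*axes_vals, indexing="ij")
        angles = np.stack([g.ravel() for g in grids], axis=1)
    elif spec.sampling == "random":
        rng = np.random.default_rng(spec.seed)
        angles = rng.uniform(-1, 1, size=(spec.n_samples, 3)) * np.array(hr)
    else:
        raise ValidationError(f"unknown sampling {spec.sampling!r}")
    if spec.mode == "coupled":
        rule = spec.coupling
        limit = rule.half_range(angles[:, rule.driving])
        angles = angles[np.abs(angles[:, rule.dependent]) <= limit + 1e-12]
    if len(angles) == 0:
        raise ValidationError("spec produced an empty sample")
    return angles


def generate_rom(spec: RomSpec) -> OrientationSet:
    """Generate an orientation dataset from a RoM spec.

    Each sampled angle tuple is composed via the declared Euler sequence;
    the result is deterministic for a given spec (and seed, when sampling
    randomly).
    """
    angles = sample_angles(spec)
    items = [
        from_euler(EulerSpec(spec.sequence, tuple(a), spec.intrinsic)) for a in angles
    ]
    return OrientationSet(items, label=f"synthetic:{spec.mode}")


# ---------------------------------------------------------------------------
# Virtual rig
# ---------------------------------------------------------------------------


@dataclass
class TorqueModel:
    """Piecewise power-law passive-torque model (per Euler axis).

    Torque is zero while |angle| <= onset and
    ``stiffness * (|angle| - onset)**exponent`` beyond, signed to oppose the
    excursion.  Defaults: onset 25 deg, stiffness 0.5 N*mm/deg^3, exponent 3.
    """

    onset_deg: tuple[float, float, float] = (25.0, 25.0, 25.0)
    stiffness: float = 0.5  # N*mm / deg**exponent
    exponent: float = 3.0

    def torque(self, angles: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(angles, float))
        excess = np.maximum(np.abs(a) - np.array(self.onset_deg), 0.0)
        return -np.sign(a) * self.stiffness * excess**self.exponent


@dataclass
class RigGeometry:
    """Constant transforms and marker layout of the virtual joint rig.

    Transforms follow the chain convention ``^A T_B`` (B coordinates into A).
    ``marker_local`` holds the marker-tree points in the markers frame (mm)
    and must be non-coplanar so a rigid pose is recoverable from a single
    frame.  The specimen-mounting transforms (bone ACS on plate) default to
    identity and are set per synthetic specimen.
    """

    pPlate_T_base: RigidTransform
    dPlate_T_markers: RigidTransform
    pACS_T_pPlate: RigidTransform = field(default_factory=RigidTransform.identity)
    dACS_T_dPlate: RigidTransform = field(default_factory=RigidTransform.identity)
    marker_local: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, 0, 0], [40.0, 0, 0], [0, 40.0, 0], [12.0, 12.0, 35.0]]
        )
    )
    torque_model: TorqueModel = field(default_factory=TorqueModel)
    torque_threshold: float = 20.0  # N*mm, feedback tone onset
    torque_upper: float = 200.0  # N*mm, top of the pitch scale

    def __post_init__(self) -> None:
        self.marker_local = np.atleast_2d(np.asarray(self.marker_local, float))
        if len(self.marker_local) < 4:
            raise ValidationError("marker tree needs >= 4 points")
        d = self.marker_local - self.marker_local.mean(axis=0)
        if np.linalg.svd(d, compute_uv=False)[2] < 1e-6:
            raise ValidationError("marker tree must be non-coplanar")
        if self.torque_threshold >= self.torque_upper:
            raise ValidationError("torque threshold must be below the upper limit")

    def pACS_T_base(self) -> RigidTransform:
        return self.pACS_T_pPlate @ self.pPlate_T_base

    def dACS_T_markers(self) -> RigidTransform:
        return self.dACS_T_dPlate @ self.dPlate_T_markers


def default_rig_geometry() -> RigGeometry:
    """A small desk-scale rig: base-to-plate and marker offsets of a few cm
    with non-trivial rotations, so chain errors cannot cancel silently."""
    from scipy.spatial.transform import Rotation as _R

    pPlate_T_base = RigidTransform.from_rt(
        _R.from_euler("XYZ", [5.0, -3.0, 10.0], degrees=True).as_matrix(),
        [30.0, -12.0, 55.0],
    )
    dPlate_T_markers = RigidTransform.from_rt(
        _R.from_euler("ZYX", [-8.0, 4.0, 2.0], degrees=True).as_matrix(),
        [-15.0, 22.0, 48.0],
    )
    pACS_T_pPlate = RigidTransform.from_rt(
        _R.from_euler("YXZ", [2.0, -6.0, 3.0], degrees=True).as_matrix(),
        [4.0, 7.0, -9.0],
    )
    dACS_T_dPlate = RigidTransform.from_rt(
        _R.from_euler("XZY", [-4.0, 5.0, -2.0], degrees=True).as_matrix(),
        [-6.0, 3.0, 11.0],
    )
    return RigGeometry(pPlate_T_base, dPlate_T_markers, pACS_T_pPlate, dACS_T_dPlate)


@dataclass
class RigSession:
    """One simulated capture session.

    ``markers`` is (frames, n_markers, 3) in base-frame mm; ``ground_truth``
    the joint orientations the marker poses were built from; ``torques``
    (frames, 3) N*mm in the joint's Euler-axis decomposition.
    """

    markers: np.ndarray
    ground_truth: OrientationSet
    angles: np.ndarray
    torques: np.ndarray
    timestamps: np.ndarray
    geometry: RigGeometry
    noise_sd: float


def simulate_session(
    spec: RomSpec,
    geom: RigGeometry,
    noise_sd: float = 0.1,
    seed: int = 0,
    rate_hz: float = 100.0,
) -> RigSession:
    """Emulate a rig capture session for every pose the spec generates.

    For each ground-truth joint pose ``dACS_T_pACS`` (pure rotation at the
    joint) the tracked marker pose is obtained by inverting the processing
    chain::

        markers_T_base = invert(dACS_T_markers) @ dACS_T_pACS @ pACS_T_base

    and the marker-tree points are placed in the base frame through
    ``invert(markers_T_base)``, then perturbed with isotropic Gaussian noise
    of ``noise_sd`` mm (default 0.1 mm, a typical optical motion-capture
    residual).  At zero noise, recovering the pose and running the forward
    chain reproduces the ground truth to machine precision.
    """
    angles = sample_angles(spec)
    truth = [
        from_euler(EulerSpec(spec.sequence, tuple(a), spec.intrinsic)) for a in angles
    ]
    rng = np.random.default_rng(seed)
    pACS_T_base = geom.pACS_T_base()
    markers_T_dACS = invert(geom.dACS_T_markers())
    frames = np.empty((len(truth), len(geom.marker_local), 3))
    for i, o in enumerate(truth):
        dACS_T_pACS = RigidTransform.from_rt(o.m)  # rows-matrix == ^d R_p block
        markers_T_base = markers_T_dACS @ dACS_T_pACS @ pACS_T_base
        base_T_markers = invert(markers_T_base)
        frames[i] = base_T_markers.apply(geom.marker_local)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    torques = geom.torque_model.torque(angles)
    ts = np.arange(len(truth)) / rate_hz
    return RigSession(
        frames,
        OrientationSet(truth, timestamps=ts, label=f"session:{spec.mode}"),
        angles,
        torques,
        ts,
        geom,
        noise_sd,
    )


# ---------------------------------------------------------------------------
# Torque classification (audio feedback logic)
# ---------------------------------------------------------------------------

TORQUE_CLASSES = ("below", "feedback-zone", "above-limit")


def classify_torque(
    session: RigSession, threshold: float | None = None, upper: float | None = None
) -> tuple[list[str], np.ndarray]:
    """Three-way torque classification per frame, plus the feedback pitch.

    Frames with torque magnitude below ``threshold`` are silent; between
    ``threshold`` (inclusive) and ``upper`` the feedback tone's normalised
    pitch fraction is ``(|tau| - threshold) / (upper - threshold)``; at or
    above ``upper`` the class is ``above-limit`` with fraction 1.
    """
    thr = session.geometry.torque_threshold if threshold is None else threshold
    up = session.geometry.torque_upper if upper is None else upper
    if thr >= up:
        raise ValidationError("threshold must be below upper")
    mag = np.linalg.norm(session.torques, axis=1)
    frac = np.clip((mag - thr) / (up - thr), 0.0, 1.0)
    labels = [
        "below" if m < thr else ("feedback-zone" if m < up else "above-limit")
        for m in mag
    ]
    return labels, frac
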