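"""File formats, configuration and logging.

Supported formats
-----------------
* Orientation tables (CSV/TSV): rotation-matrix columns ``r11..r33``,
  quaternion columns ``qw,qx,qy,qz``, or Euler columns ``seq,a1,a2,a3``
  (degrees; an uppercase sequence such as ``ZYX`` declares intrinsic
  composition, lowercase extrinsic).
* Qualisys-style marker TSV: a small header (frame count, marker count,
  frequency, marker names) followed by tab-separated x/y/z triplets per
  marker per row; occluded markers are empty or NaN fields.
* JSON: configuration, landmark sets, rig constant transforms, and SFP
  exports (polygon vertices, areas, metadata).
* OBJ: triangulated polygon fans on the sphere for 3D viewers.
* PNG: rendered three-polygon sphere with the null-pose frame at the centre
  (X red, Y green, Z blue).

Numeric precision: 12 significant digits in CSV/TSV, full double in JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .orientations import (
    EulerSpec,
    Orientation,
    OrientationSet,
    UnitQuaternion,
    from_euler,
    from_quaternion,
    to_quaternion,
)
from .sfp import SFP
from .spherical import SphericalPolygon
from .transforms import LandmarkSet, RigidTransform, invert

logger = logging.getLogger("sfproj")

CSV_PRECISION = 12

_MATRIX_COLS = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_EULER_COLS = ["seq", "a1", "a2", "a3"]


@contextmanager
def stage(name: str, **fields):
    """Structured per-stage log record with wall-clock timing."""
    t0 = time.perf_counter()
    logger.info("stage=%s status=start %s", name, _kv(fields))
    try:
        yield
    except Exception as e:
        logger.error("stage=%s status=error error=%r", name, e)
        raise
    logger.info(
        "stage=%s status=done elapsed_s=%.3f %s", name, time.perf_counter() - t0, _kv(fields)
    )


def _kv(fields: dict) -> str:
    return " ".join(f"{k}={v}" for k, v in fields.items())


def file_hash(path) -> str:
    """SHA-256 of a file, for provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Pipeline configuration with documented valid ranges.

    All values round-trip through JSON exactly.
    """

    euler_sequence: str = "ZYX"
    euler_intrinsic: bool = True
    resolution: int = 1280  # boundary-fit patches; 20..327680
    dilation: int = 0  # rings; >= 0
    path_k: int = 6  # >= 1
    path_step_max: float = 10.0  # degrees; > 0
    orthonormality_tol: float = 1e-9
    length_unit: str = "mm"
    output_format: str = "json"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20 <= self.resolution <= 20 * 4**7):
            raise ValidationError("resolution out of range [20, 20*4^7]")
        if self.dilation < 0 or self.path_k < 1 or self.path_step_max <= 0:
            raise ValidationError("dilation >= 0, path_k >= 1, path_step_max > 0 required")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "Config":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Orientation tables
# ---------------------------------------------------------------------------


def read_orientations(path, format_hint: str | None = None) -> OrientationSet:
    """Read an orientation table; the header row declares the representation.

    ``format_hint`` (``"matrix"``, ``"quaternion"``, ``"euler"``) skips the
    column sniffing.  Malformed or invalid rows are collected and reported
    together with their line numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    rep = format_hint or _sniff_representation(df.columns)
    errors: list[str] = []
    items: list[Orientation] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            items.append(_parse_row(row, rep))
        except Exception as e:
            errors.append(f"line {line}: {e}")
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {path.name}:\n" + "\n".join(errors)
        )
    if not items:
        raise FormatError(f"{path.name} contains no data rows")
    ts = df["t"].to_numpy(float) if "t" in df.columns else None
    return OrientationSet(items, timestamps=ts, label=path.name)


def _sniff_representation(columns) -> str:
    cols = set(columns)
    if cols.issuperset(_MATRIX_COLS):
        return "matrix"
    if cols.issuperset(_QUAT_COLS):
        return "quaternion"
    if cols.issuperset(_EULER_COLS):
        return "euler"
    raise FormatError(
        "unknown representation: expected columns r11..r33, qw..qz, or seq,a1,a2,a3; "
        f"found {sorted(cols)}"
    )


def _parse_row(row, rep: str) -> Orientation:
    if rep == "matrix":
        m = np.array([float(row[c]) for c in _MATRIX_COLS]).reshape(3, 3)
        return Orientation(m)
    if rep == "quaternion":
        return from_quaternion(
            UnitQuaternion(*(float(row[c]) for c in _QUAT_COLS))
        )
    if rep == "euler":
        seq = str(row["seq"]).strip()
        return from_euler(
            EulerSpec(seq, tuple(float(row[c]) for c in ("a1", "a2", "a3")), seq.isupper())
        )
    raise FormatError(f"unknown representation {rep!r}")


def write_orientations(path, data: OrientationSet, representation: str = "matrix") -> None:
    """Write an orientation table in the requested representation."""
    path = Path(path)
    fmt = f"%.{CSV_PRECISION}g"
    rows = []
    for o in data:
        if representation == "matrix":
            rows.append({c: v for c, v in zip(_MATRIX_COLS, o.m.ravel())})
        elif representation == "quaternion":
            q = to_quaternion(o)
            rows.append(dict(zip(_QUAT_COLS, q.as_array())))
        else:
            raise FormatError(f"unsupported output representation {representation!r}")
    df = pd.DataFrame(rows)
    if data.timestamps is not None:
        df.insert(0, "t", data.timestamps)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# Qualisys-style marker TSV and pose recovery
# ---------------------------------------------------------------------------


def write_session_tsv(path, markers: np.ndarray, names=None, frequency: float = 100.0) -> None:
    """Write (frames, n_markers, 3) marker trajectories as a Qualisys-style TSV."""
    path = Path(path)
    markers = np.asarray(markers, float)
    n_frames, n_markers, _ = markers.shape
    names = names or [f"m{i+1}" for i in range(n_markers)]
    fmt = f"%.{CSV_PRECISION}g"
    with path.open("w") as f:
        f.write(f"NO_OF_FRAMES\t{n_frames}\n")
        f.write(f"NO_OF_MARKERS\t{n_markers}\n")
        f.write(f"FREQUENCY\t{frequency}\n")
        f.write("MARKER_NAMES\t" + "\t".join(names) + "\n")
        for fr in markers:
            vals = []
            for m in fr:
                if np.any(np.isnan(m)):
                    vals += ["", "", ""]
                else:
                    vals += [fmt % v for v in m]
            f.write("\t".join(vals) + "\n")


@dataclass
class PoseStream:
    """Recovered rigid-body poses: per retained frame, ``markers_T_base``
    (base coordinates into the marker frame), occlusion flags, and the
    indices of frames dropped for having fewer than three visible markers."""

    transforms: list[RigidTransform]
    occluded_flags: list[bool]
    frame_indices: list[int]
    dropped: list[int]
    frequency: float = 100.0


def read_mocap(path, marker_local: np.ndarray) -> PoseStream:
    """Read a Qualisys-style TSV and fit per-frame rigid-body poses.

    Each frame's visible markers are matched to the marker-tree model
    ``marker_local`` by an orthogonal Procrustes (Kabsch) fit, giving the
    base pose of the tree and hence ``markers_T_base``.  Frames with one
    occluded marker (of >= 4) are still solved but flagged; frames with
    fewer than three visible markers are dropped with a warning.
    """
    path = Path(path)
    marker_local = np.atleast_2d(np.asarray(marker_local, float))
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    data_start = 0
    for i, ln in enumerate(lines):
        parts = ln.split("\t")
        key = parts[0].strip().upper()
        if key in ("NO_OF_FRAMES", "NO_OF_MARKERS", "FREQUENCY", "MARKER_NAMES"):
            header[key] = parts[1] if len(parts) > 1 else ""
            data_start = i + 1
        else:
            break
    if "NO_OF_MARKERS" not in header:
        raise FormatError(f"{path.name}: missing Qualisys-style header")
    n_markers = int(header["NO_OF_MARKERS"])
    if n_markers != len(marker_local):
        raise FormatError(
            f"file has {n_markers} markers but the model has {len(marker_local)}"
        )
    freq = float(header.get("FREQUENCY", 100.0))
    transforms, flags, kept, dropped = [], [], [], []
    for fi, ln in enumerate(lines[data_start:]):
        if not ln.strip():
            continue
        vals = ln.split("\t")
        pts = np.full((n_markers, 3), np.nan)
        for m in range(n_markers):
            trip = vals[3 * m : 3 * m + 3]
            if len(trip) == 3 and all(t.strip() for t in trip):
                pts[m] = [float(t) for t in trip]
        visible = ~np.isnan(pts).any(axis=1)
        if visible.sum() < 3:
            logger.warning("frame %d dropped: only %d visible markers", fi, visible.sum())
            dropped.append(fi)
            continue
        R, t = _kabsch(marker_local[visible], pts[visible])
        base_T_markers = RigidTransform.from_rt(R, t)
        transforms.append(invert(base_T_markers))
        flags.append(bool((~visible).any()))
        kept.append(fi)
    if not transforms:
        raise FormatError(f"{path.name}: all frames occluded; no poses recovered")
    return PoseStream(transforms, flags, kept, dropped, freq)


def _kabsch(local: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit: R @ local + t ~= observed."""
    cl = local.mean(axis=0)
    co = observed.mean(axis=0)
    H = (local - cl).T @ (observed - co)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, co - R @ cl


# ---------------------------------------------------------------------------
# Landmarks and rig transforms
# ---------------------------------------------------------------------------


def read_landmarks(path) -> LandmarkSet:
    """Landmark points from JSON ({group: [[x,y,z],...]}) or CSV with columns
    label, group, x, y, z."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return LandmarkSet({k: np.asarray(v, float) for k, v in raw.items()})
    df = pd.read_csv(path)
    needed = {"group", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise FormatError(f"landmark CSV needs columns {sorted(needed)}")
    return LandmarkSet(
        {g: sub[["x", "y", "z"]].to_numpy(float) for g, sub in df.groupby("group", sort=False)}
    )


def read_rig_transforms(path) -> dict[str, RigidTransform]:
    """Named constant rig transforms from a JSON of 4x4 matrices."""
    raw = json.loads(Path(path).read_text())
    return {name: RigidTransform(np.asarray(m, float)) for name, m in raw.items()}


def write_rig_transforms(path, transforms: dict[str, RigidTransform]) -> None:
    Path(path).write_text(
        json.dumps({k: v.matrix.tolist() for k, v in transforms.items()}, indent=2)
    )


# ---------------------------------------------------------------------------
# SFP export and rendering
# ---------------------------------------------------------------------------


def sfp_to_json(path, sfp: SFP) -> None:
    Path(path).write_text(json.dumps(sfp.to_dict(), indent=2))


def sfp_from_json(path) -> SFP:
    raw = json.loads(Path(path).read_text())
    polys = {
        a: SphericalPolygon(np.asarray(p["vertices"]), np.asarray(p["interior_point"]))
        for a, p in raw["polygons"].items()
    }
    return SFP(polys, Orientation(np.asarray(raw["null_pose"])), raw.get("metadata", {}))


def sfp_to_obj(path, sfp: SFP) -> None:
    """Export the three polygons as triangle fans (OBJ) for 3D viewers."""
    lines = ["# sfproj spherical frame projection"]
    offset = 0
    for axis in ("X", "Y", "Z"):
        poly = sfp.polygons[axis]
        lines.append(f"o polygon_{axis}")
        c = poly.interior_point
        lines.append("v " + " ".join(f"{x:.9f}" for x in c))
        for v in poly.vertices:
            lines.append("v " + " ".join(f"{x:.9f}" for x in v))
        n = len(poly.vertices)
        for i in range(n):
            a = offset + 2 + i
            b = offset + 2 + (i + 1) % n
            lines.append(f"f {offset + 1} {a} {b}")
        offset += n + 1
    Path(path).write_text("\n".join(lines) + "\n")


_AXIS_COLOURS = {"X": "tab:red", "Y": "tab:green", "Z": "tab:blue"}


def render_sfp(path, sfp: SFP, trace=None, dpi: int = 120) -> None:
    """Render the three-polygon sphere with the null-pose frame at centre.

    X is drawn red, Y green, Z blue.  ``trace`` (a FrameTrace) optionally
    overlays the source point clouds.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="3d")
    u, v = np.mgrid[0 : 2 * np.pi : 40j, 0 : np.pi : 20j]
    ax.plot_wireframe(
        np.cos(u) * np.sin(v), np.sin(u) * np.sin(v), np.cos(v),
        color="lightgray", linewidth=0.3, alpha=0.5,
    )
    for axis, colour in _AXIS_COLOURS.items():
        poly = sfp.polygons[axis]
        dense = _densify(poly.vertices)
        ax.plot(dense[:, 0], dense[:, 1], dense[:, 2], color=colour, linewidth=1.5)
        if trace is not None:
            pts = trace.clouds[axis]
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=2, color=colour, alpha=0.4)
    for i, (axis, colour) in enumerate(_AXIS_COLOURS.items()):
        e = sfp.null_pose.m[i]
        ax.quiver(0, 0, 0, *e, color=colour, arrow_length_ratio=0.08)
    ax.set_box_aspect((1, 1, 1))
    ax.set_xlabel("1")
    ax.set_ylabel("1")
    ax.set_zlabel("1")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def _densify(vertices: np.ndarray, per_edge: int = 8) -> np.ndarray:
    from .spherical import slerp

    out = []
    n = len(vertices)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        for t in np.linspace(0, 1, per_edge, endpoint=False):
            out.append(slerp(a, b, t))
    out.append(vertices[0])
    return np.array(out)
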