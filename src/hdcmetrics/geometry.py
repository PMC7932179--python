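"""3D constructions underlying all cannulation metrics.

The simulator is calibrated by touching an electromagnetically tracked
stylus to known landmarks: several points on the artificial skin surface,
and the four corners of the (planar, elongated) mid-plane rectangle of the
straight artificial fistula.  From those measurements this module builds

* the skin-surface plane (total-least-squares fit),
* the fistula frame: fitted fistula plane, axial line through the midpoints
  of the rectangle's short sides, an in-plane lateral unit vector and the
  upward plane normal, plus the lumen radius,
* the needle-tip position from each 6-DOF sensor pose
  (``P_tip = P_sensor + R @ d``), and
* the projections (onto a plane, onto the axis, onto the cross-sectional
  plane of the fistula) that the process and outcome metrics consume.

Units are millimetres and seconds throughout; the tracker field frame has
Z pointing vertically up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AmbiguousAxisError, DegenerateGeometryError, InvalidPoseError

__all__ = [
    "PoseSample",
    "TipOffset",
    "Plane",
    "FistulaFrame",
    "SimGeometry",
    "tip_position",
    "fit_plane",
    "build_fistula_frame",
    "project_to_plane",
    "project_to_axis",
    "cross_section_coords",
]

_QUAT_TOL = 1e-6


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


@dataclass(frozen=True)
class PoseSample:
    """One timestamped 6-DOF sensor reading.

    Parameters
    ----------
    t : float
        Seconds since trial start (finite, non-negative).
    position : (3,) array
        Sensor position in the tracker field frame, mm.
    quaternion : (4,) array
        Scalar-first unit quaternion (w, x, y, z) rotating sensor-frame
        vectors into the tracker field frame.
    """

    t: float
    position: np.ndarray
    quaternion: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position, "position"))
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components (w, x, y, z)")
        object.__setattr__(self, "quaternion", q)
        if not (np.isfinite(self.t) and self.t >= 0):
            raise ValueError("t must be finite and non-negative")

    def rotation(self) -> Rotation:
        """Orientation as a scipy Rotation; validates unit norm."""
        q = self.quaternion
        norm = float(np.linalg.norm(q))
        if abs(norm - 1.0) > _QUAT_TOL:
            raise InvalidPoseError(
                f"quaternion norm {norm:.9f} deviates from 1 beyond {_QUAT_TOL}"
            )
        qn = q / norm
        # scipy expects scalar-last
        return Rotation.from_quat([qn[1], qn[2], qn[3], qn[0]])

    def rotation_matrix(self) -> np.ndarray:
        return self.rotation().as_matrix()


@dataclass(frozen=True)
class TipOffset:
    """Needle-tip offset from the embedded sensor, in the sensor frame (mm)."""

    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "d", _as_vec3(self.d, "tip offset"))


@dataclass(frozen=True)
class Plane:
    """Plane ``a x + b y + c z + d = 0`` with unit normal ``(a, b, c)``.

    Sign convention: the vertical (Z) normal component is non-negative; for
    planes with |c| <= 1e-9 the convention falls back lexicographically to
    b >= 0, then a >= 0, so "up" is consistent across trials.
    """

    normal: np.ndarray
    d: float

    def __post_init__(self):
        n = _as_vec3(self.normal, "normal")
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    @property
    def a(self) -> float:
        return float(self.normal[0])

    @property
    def b(self) -> float:
        return float(self.normal[1])

    @property
    def c(self) -> float:
        return float(self.normal[2])

    @classmethod
    def from_coefficients(cls, a: float, b: float, c: float, d: float) -> "Plane":
        n = np.array([a, b, c], dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise DegenerateGeometryError("zero plane normal")
        n, d = n / norm, d / norm
        n, d = _orient(n, d)
        return cls(n, float(d))

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance(s); positive on the normal side."""
        p = np.asarray(points, dtype=float)
        return p @ self.normal + self.d

    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])


def _orient(n: np.ndarray, d: float):
    """Apply the vertical-up sign convention to (n, d)."""
    for i in (2, 1, 0):
        if abs(n[i]) > 1e-9:
            if n[i] < 0:
                return -n, -d
            return n, d
    return n, d


@dataclass(frozen=True)
class FistulaFrame:
    """Calibrated frame of the straight artificial fistula.

    ``axis_start`` (P_e) and ``axis_end`` (P_f) are the midpoints of the
    short sides of the measured mid-plane rectangle, projected exactly onto
    the fitted fistula plane.  The cross-sectional plane is perpendicular to
    the axis with P_e as its origin; ``u_lat`` is the in-plane lateral unit
    vector (cross-section x), ``v_vert`` the upward plane normal
    (cross-section y).  The basis (axis, u_lat, v_vert) is right-handed.
    """

    vertices: np.ndarray  # (4, 3) as measured
    plane: Plane
    axis_start: np.ndarray
    axis_end: np.ndarray
    u_lat: np.ndarray
    v_vert: np.ndarray
    radius: float
    length: float = field(default=float("nan"))

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("fistula radius must be positive")

    @property
    def axis_direction(self) -> np.ndarray:
        v = self.axis_end - self.axis_start
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SimGeometry:
    """Full calibrated simulator geometry used by the analysis pipeline."""

    skin: Plane
    frame: FistulaFrame
    tip_offset: TipOffset
    skin_points: np.ndarray | None = None


def tip_position(sample: PoseSample, offset: TipOffset) -> np.ndarray:
    """Needle-tip position ``P_sensor + R @ d`` for one pose sample (mm)."""
    return sample.position + sample.rotation_matrix() @ offset.d


def fit_plane(points) -> Plane:
    """Total-least-squares plane through >= 3 non-collinear points.

    Minimizes the sum of squared orthogonal distances (SVD of the centered
    point cloud; the normal is the left singular vector of the smallest
    singular value).  Raises :class:`DegenerateGeometryError` for fewer than
    three points or a (near-)collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points of dimension 3")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError("plane fit received non-finite points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] <= 1e-10 * scale or s[0] == 0:
        raise DegenerateGeometryError("points are collinear; plane is undetermined")
    n = vt[2]
    d = -float(n @ centroid)
    n, d = _orient(n, d)
    return Plane(n, d)


def build_fistula_frame(vertices, radius: float, length: float | None = None) -> FistulaFrame:
    """Construct the fistula frame from the four measured plane vertices.

    The plane is fitted over all four vertices by total least squares; the
    axial line runs through the midpoints of the two short sides.  The
    quadrilateral must be elongated (ratio of opposite-side mean lengths
    >= 1.5), otherwise the axis is ambiguous.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.shape != (4, 3):
        raise DegenerateGeometryError("fistula frame needs exactly 4 vertices")
    plane = fit_plane(verts)
    proj = np.array([project_to_plane(v, plane) for v in verts])

    # sides in vertex order: (0-1, 1-2, 2-3, 3-0); opposite pairs (0,2) and (1,3)
    side_len = np.array(
        [np.linalg.norm(proj[(i + 1) % 4] - proj[i]) for i in range(4)]
    )
    pair_a = 0.5 * (side_len[0] + side_len[2])  # sides 0-1 and 2-3
    pair_b = 0.5 * (side_len[1] + side_len[3])  # sides 1-2 and 3-0
    if min(pair_a, pair_b) <= 0:
        raise DegenerateGeometryError("degenerate quadrilateral side of zero length")
    ratio = max(pair_a, pair_b) / min(pair_a, pair_b)
    if ratio < 1.5:
        raise AmbiguousAxisError(
            f"quadrilateral aspect ratio {ratio:.3f} < 1.5; fistula axis is ambiguous"
        )
    if pair_a < pair_b:
        # sides 0-1 and 2-3 are the short sides
        p_e = 0.5 * (proj[0] + proj[1])
        p_f = 0.5 * (proj[2] + proj[3])
    else:
        p_e = 0.5 * (proj[1] + proj[2])
        p_f = 0.5 * (proj[3] + proj[0])

    axis = p_f - p_e
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-9:
        raise DegenerateGeometryError("coincident short-side midpoints")
    axis = axis / axis_norm
    # deterministic axis orientation: largest-|component| coordinate positive
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
        p_e, p_f = p_f, p_e

    v_vert = plane.normal  # already oriented upward by convention
    u_lat = np.cross(v_vert, axis)
    u_lat = u_lat / np.linalg.norm(u_lat)
    if length is None:
        length = float(np.linalg.norm(p_f - p_e))
    return FistulaFrame(
        vertices=verts,
        plane=plane,
        axis_start=p_e,
        axis_end=p_f,
        u_lat=u_lat,
        v_vert=v_vert,
        radius=float(radius),
        length=float(length),
    )


def project_to_plane(point, plane: Plane) -> np.ndarray:
    """Orthogonal foot of ``point`` on ``plane``."""
    p = _as_vec3(point, "point")
    return p - plane.signed_distance(p) * plane.normal


def project_to_axis(point, frame: FistulaFrame) -> np.ndarray:
    """Nearest point on the (infinite) fistula axial line."""
    p = _as_vec3(point, "point")
    a = frame.axis_direction
    rel = p - frame.axis_start
    return frame.axis_start + (rel @ a) * a


def cross_section_coords(point, frame: FistulaFrame) -> tuple[float, float]:
    """Project ``point`` along the axis onto the cross-sectional plane at P_e.

    Returns (x, y) with x the lateral component along ``u_lat`` and y the
    vertical component along ``v_vert``; the origin is the lumen axis, so
    sqrt(x^2 + y^2) is the distance of the point from the axis.
    """
    p = _as_vec3(point, "point")
    rel = p - frame.axis_start
    return float(rel @ frame.u_lat), float(rel @ frame.v_vert)
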