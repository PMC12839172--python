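"""Planes, rigid transforms and distance/angle primitives.

Everything downstream (reference-frame construction, registration,
resection-plane deviations, cephalometric measurements) is expressed in
terms of the small vocabulary defined here: a plane as point + unit
normal, a proper rigid transform, least-squares plane and rigid fits,
and extremal ("tangent-plane contact") vertex queries.

All coordinates are millimetres; all angles returned in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "PlanarPatch",
    "RigidTransform",
    "plane_from_points",
    "fit_plane",
    "angle_between_planes",
    "dihedral_angle",
    "angle_line_plane",
    "extremal_point",
    "signed_distance",
    "point_to_line_distance",
    "rigid_fit",
]

_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives geometrically degenerate input."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _UNIT_TOL:
        raise DegenerateGeometryError("cannot normalize a near-zero vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Infinite plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        n = _as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            n = _normalize(n)
        object.__setattr__(self, "normal", n)

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)

    def oriented_towards(self, p) -> "Plane":
        """Return a copy whose normal has positive signed distance to ``p``."""
        return self if signed_distance(self, p) >= 0.0 else self.flipped()


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (rotation + translation, no reflection)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must have determinant +1")
        self.rotation, self.translation = R, t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_plane(self, plane: Plane) -> Plane:
        return Plane(self.apply(plane.point), self.rotation @ plane.normal)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three points; normal = cross(p2-p1, p3-p1), normalized."""
    p1, p2, p3 = _as_point(p1), _as_point(p2), _as_point(p3)
    n = np.cross(p2 - p1, p3 - p1)
    area2 = np.linalg.norm(n)
    if area2 / 2.0 <= 1e-9:
        raise DegenerateGeometryError("points are collinear (triangle area <= 1e-9)")
    return Plane(p1, n / area2)


def fit_plane(points) -> tuple[Plane, float]:
    """Least-squares plane through >= 3 points.

    The normal is the direction of smallest spread about the centroid
    (smallest right-singular vector of the centered coordinates); the
    second return value is the RMS orthogonal distance of the points to
    the fitted plane.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: smallest singular direction = normal.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise DegenerateGeometryError("points are collinear; plane fit is rank-deficient")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(centroid, normal), rms


@dataclass
class PlanarPatch:
    """A bounded, approximately planar triangulated region with its fitted plane.

    ``mesh`` is any object with ``vertices``/``faces`` arrays (see
    :mod:`mandiblemetrics.mesh_io`). Vertices must lie within
    ``max_planarity_tol`` of the fitted plane.
    """

    mesh: object
    fitted_plane: Plane
    rms_residual: float

    @classmethod
    def from_mesh(cls, mesh, max_planarity_tol: float = 1.0) -> "PlanarPatch":
        plane, rms = fit_plane(np.asarray(mesh.vertices, dtype=float))
        d = np.abs((np.asarray(mesh.vertices) - plane.point) @ plane.normal)
        worst = float(d.max())
        if worst > max_planarity_tol:
            raise DegenerateGeometryError(
                f"patch is not planar: worst vertex {worst:.3f} mm from fitted plane "
                f"(tolerance {max_planarity_tol} mm)"
            )
        return cls(mesh=mesh, fitted_plane=plane, rms_residual=rms)


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Folded angle between two planes, degrees in [0, 90]; flip-invariant."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def dihedral_angle(a: Plane, b: Plane) -> float:
    """Interior angle between two half-planes with *outward* normals.

    Returns 180° − angle(n_a, n_b), in (0, 180). The anatomical gonial
    angle (~120°) follows this convention.
    """
    d = float(np.clip(np.dot(a.normal, b.normal), -1.0, 1.0))
    if abs(d) >= 1.0 - 1e-12:
        raise DegenerateGeometryError("planes are parallel; dihedral angle undefined")
    return 180.0 - float(np.degrees(np.arccos(d)))


def angle_line_plane(direction, plane: Plane) -> float:
    """Angle between a line direction and a plane, degrees in [0, 90]."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < _UNIT_TOL:
        raise DegenerateGeometryError("zero direction vector")
    s = abs(float(np.dot(d / n, plane.normal)))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def extremal_point(mesh, direction, roi=None) -> tuple[np.ndarray, int]:
    """Vertex maximizing ``dot(v, direction)``, optionally restricted to a ROI.

    This is the mesh equivalent of sliding a tangent plane with normal
    ``direction`` against the surface. Ties are broken by lowest vertex
    index (``np.argmax`` returns the first maximum). Returns (point, index),
    the index referring to the full mesh vertex array.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if verts.shape[0] == 0:
        raise DegenerateGeometryError("empty mesh")
    d = _normalize(np.asarray(direction, dtype=float))
    if roi is not None:
        roi = np.asarray(roi, dtype=int)
        if roi.size == 0:
            raise DegenerateGeometryError("empty ROI")
        sub = verts[roi]
        k = int(np.argmax(sub @ d))
        idx = int(roi[k])
    else:
        idx = int(np.argmax(verts @ d))
    return verts[idx].copy(), idx


def signed_distance(plane: Plane, p) -> float:
    """(p − plane.point) · normal; positive on the normal side."""
    return float(np.dot(_as_point(p) - plane.point, plane.normal))


def point_to_line_distance(p, a, b) -> float:
    """Distance from point ``p`` to the infinite line through ``a`` and ``b``."""
    p, a, b = _as_point(p), _as_point(a), _as_point(b)
    ab = b - a
    n = np.linalg.norm(ab)
    if n < _UNIT_TOL:
        raise DegenerateGeometryError("line endpoints coincide")
    return float(np.linalg.norm(np.cross(p - a, ab)) / n)


def rigid_fit(source_points, target_points) -> RigidTransform:
    """Least-squares proper rigid transform mapping source onto target (Kabsch).

    Minimizes sum |R s_i + t − g_i|^2 over rotations with det(R) = +1;
    a reflection in the SVD solution is corrected by flipping the sign of
    the smallest singular direction.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3 or src.shape[0] < 3:
        raise DegenerateGeometryError("need equal-length (>=3) 3D correspondences")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12:
        raise DegenerateGeometryError("correspondences are collinear; rotation underdetermined")
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return RigidTransform(R, t)
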