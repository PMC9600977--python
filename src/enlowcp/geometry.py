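"""Exact 2D/3D vector-geometry primitives for cephalometric constructions.

All coordinates are millimetres. 2D lateral-cephalogram frame:
x posterior→anterior, y inferior→superior. 3D canonical (CBCT) frame:
x left→right, y posterior→anterior, z inferior→superior.

Lines are stored as anchor + unit direction (vertical lines need no special
case); planes as anchor + unit normal with a provenance tag recording which
of the three construction rules produced them:

* ``three_points`` — plane through three non-collinear points,
* ``two_points_normal`` — plane through two points, perpendicular to a
  reference plane,
* ``point_parallel`` — plane through one point, parallel to a reference
  plane.

These three rules are the complete construction vocabulary of the 3D
analysis; every measurement downstream is a point-to-plane distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "GeometryTolerances",
    "tolerances",
    "set_geometry_tolerances",
    "Point2",
    "Point3",
    "Line2",
    "Plane3",
    "line_through",
    "line_parallel_through",
    "intersect_lines",
    "project_point_onto_line",
    "plane_from_three_points",
    "plane_from_two_points_normal",
    "plane_parallel_through_point",
    "point_plane_distance",
]


@dataclass
class GeometryTolerances:
    """Global degeneracy tolerances.

    point_mm: below this separation two points count as coincident and a
        triangle as degenerate (mm, and mm^2 for areas).
    angle_rad: below this angle two directions count as parallel.
    """

    point_mm: float = 1e-9
    angle_rad: float = 1e-6


#: Module-level tolerance settings; mutate via :func:`set_geometry_tolerances`.
tolerances = GeometryTolerances()


def set_geometry_tolerances(point_mm: float | None = None,
                            angle_rad: float | None = None) -> None:
    if point_mm is not None:
        tolerances.point_mm = float(point_mm)
    if angle_rad is not None:
        tolerances.angle_rad = float(angle_rad)


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar (z) cross product of two 2D vectors."""
    return float(a[0] * b[1] - a[1] * b[0])


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n <= tolerances.point_mm:
        raise DegenerateGeometryError(f"cannot normalize near-zero {what}")
    return v / n


@dataclass(frozen=True)
class Point2:
    """A 2D landmark position (mm): x posterior→anterior, y inferior→superior."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite 2D coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def from_array(a) -> "Point2":
        a = np.asarray(a, dtype=float)
        return Point2(float(a[0]), float(a[1]))


@dataclass(frozen=True)
class Point3:
    """A 3D landmark position (mm): x left→right, y posterior→anterior,
    z inferior→superior."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError(
                f"non-finite 3D coordinates ({self.x}, {self.y}, {self.z})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Point3":
        a = np.asarray(a, dtype=float)
        return Point3(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class Line2:
    """Oriented 2D line: anchor point plus unit direction."""

    anchor: Point2
    direction: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"line direction not unit length (|d| = {n})")

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    def point_at(self, t: float) -> Point2:
        return Point2.from_array(self.anchor.as_array() + t * self.d)

    def coordinate_of(self, p: Point2) -> float:
        """Scalar position of the projection of ``p`` along the line."""
        return float((p.as_array() - self.anchor.as_array()) @ self.d)

    def contains(self, p: Point2, tol: float | None = None) -> bool:
        tol = tolerances.point_mm if tol is None else tol
        v = p.as_array() - self.anchor.as_array()
        return abs(_cross2(v, self.d)) <= tol


@dataclass(frozen=True)
class Plane3:
    """Oriented 3D plane: anchor point, unit normal, construction provenance."""

    anchor: Point3
    normal: tuple[float, float, float]
    provenance: str = "three_points"

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        ln = float(np.linalg.norm(n))
        if abs(ln - 1.0) > 1e-9:
            raise ValueError(f"plane normal not unit length (|n| = {ln})")
        if self.provenance not in ("three_points", "two_points_normal",
                                   "point_parallel", "canonical"):
            raise ValueError(f"unknown plane provenance {self.provenance!r}")

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    def signed_distance(self, p: Point3) -> float:
        return float(self.n @ (p.as_array() - self.anchor.as_array()))

    def contains(self, p: Point3, tol: float | None = None) -> bool:
        tol = tolerances.point_mm if tol is None else tol
        return abs(self.signed_distance(p)) <= tol


# ---------------------------------------------------------------------------
# 2D line operations
# ---------------------------------------------------------------------------

def line_through(p: Point2, q: Point2,
                 names: tuple[str, str] | None = None) -> Line2:
    """Line through two distinct points, oriented p→q.

    ``names`` (optional landmark names) improve the degeneracy message.
    """
    v = q.as_array() - p.as_array()
    if float(np.linalg.norm(v)) <= tolerances.point_mm:
        label = " and ".join(names) if names else f"{p} and {q}"
        raise DegenerateGeometryError(
            f"coincident points defining a line: {label}")
    d = _unit(v, "line direction")
    return Line2(anchor=p, direction=(float(d[0]), float(d[1])))


def line_parallel_through(p: Point2, ref: Line2) -> Line2:
    """Line through ``p`` parallel to ``ref`` (same direction)."""
    return Line2(anchor=p, direction=ref.direction)


def intersect_lines(a: Line2, b: Line2,
                    names: tuple[str, str] | None = None) -> Point2:
    """Intersection point of two non-parallel 2D lines."""
    cross = _cross2(a.d, b.d)
    if abs(cross) <= tolerances.point_mm:
        label = " with ".join(names) if names else "two lines"
        raise DegenerateGeometryError(
            f"parallel or coincident lines cannot be intersected: {label}")
    # solve a.anchor + t*a.d = b.anchor + s*b.d for t
    rhs = b.anchor.as_array() - a.anchor.as_array()
    t = _cross2(rhs, b.d) / cross
    return a.point_at(t)


def project_point_onto_line(p: Point2, l: Line2) -> Point2:
    """Orthogonal projection of ``p`` onto ``l``."""
    return l.point_at(l.coordinate_of(p))


# ---------------------------------------------------------------------------
# 3D plane constructions (the three rules)
# ---------------------------------------------------------------------------

def plane_from_three_points(p1: Point3, p2: Point3, p3: Point3,
                            names: tuple[str, ...] | None = None) -> Plane3:
    """Plane through three non-collinear points.

    Normal follows the right-hand rule over (p2−p1)×(p3−p1), so signed
    distances are reproducible from the point ordering.
    """
    a, b, c = p1.as_array(), p2.as_array(), p3.as_array()
    n = np.cross(b - a, c - a)
    if float(np.linalg.norm(n)) <= 2.0 * tolerances.point_mm:  # 2*area
        label = ", ".join(names) if names else f"{p1}, {p2}, {p3}"
        raise DegenerateGeometryError(
            f"collinear or coincident points defining a plane: {label}")
    n = _unit(n, "plane normal")
    return Plane3(anchor=p1, normal=(float(n[0]), float(n[1]), float(n[2])),
                  provenance="three_points")


def plane_from_two_points_normal(p1: Point3, p2: Point3, ref: Plane3,
                                 names: tuple[str, str] | None = None) -> Plane3:
    """Plane through p1 and p2, perpendicular to the reference plane.

    The result contains both points and the direction of ``ref``'s normal;
    its own normal is orthogonal to ``ref.normal``. Underdetermined when the
    segment p1p2 is parallel to ``ref``'s normal.
    """
    seg = p2.as_array() - p1.as_array()
    seg_len = float(np.linalg.norm(seg))
    label = " and ".join(names) if names else f"{p1} and {p2}"
    if seg_len <= tolerances.point_mm:
        raise DegenerateGeometryError(
            f"coincident points defining a perpendicular plane: {label}")
    seg_u = seg / seg_len
    sin_angle = float(np.linalg.norm(np.cross(seg_u, ref.n)))
    if sin_angle <= tolerances.angle_rad:
        raise DegenerateGeometryError(
            "segment parallel to the reference normal; perpendicular plane "
            f"through {label} is underdetermined")
    n = _unit(np.cross(seg_u, ref.n), "plane normal")
    return Plane3(anchor=p1, normal=(float(n[0]), float(n[1]), float(n[2])),
                  provenance="two_points_normal")


def plane_parallel_through_point(p: Point3, ref: Plane3) -> Plane3:
    """Plane through ``p`` parallel to ``ref`` (normal copied verbatim)."""
    return Plane3(anchor=p, normal=ref.normal, provenance="point_parallel")


def point_plane_distance(p: Point3, plane: Plane3, signed: bool = False) -> float:
    """Distance (mm) from a point to a plane; unsigned by default.

    Signed mode uses the plane's stored normal orientation, which is fixed
    by the construction rule that produced it.
    """
    d = plane.signed_distance(p)
    return d if signed else abs(d)


# ---------------------------------------------------------------------------
# Rigid motions (used by the orientation frame and by invariance tests)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform3:
    """Proper rigid motion p ↦ R p + t in 3D."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is a reflection (det < 0)")

    def apply(self, p: Point3) -> Point3:
        return Point3.from_array(self.rotation @ p.as_array() + self.translation)

    def inverse(self) -> "RigidTransform3":
        Rt = self.rotation.T
        return RigidTransform3(Rt, -Rt @ self.translation)
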