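"""3D horizontal counterpart analysis on CBCT landmark coordinates.

The 3D analysis replaces the radiographically constructed points of the 2D
tracing with purely anatomical landmarks and replaces along-line distances
with point-to-plane distances:

=========================  ===================================================
maxillary skeletal arch    A to the PNS plane (through PNS ∥ coronal plane)
mandibular skeletal arch   B to the lingual-tuberosity plane (through rLT and
                           lLT, perpendicular to the axial plane)
maxillary dental arch      SPr to the PNS plane
mandibular dental arch     IPr to the lingual-tuberosity plane
middle cranial floor       Ba to the clinoid plane (through the two anterior
                           clinoid processes, perpendicular to the axial plane)
mandibular ramus (r/l)     rCo / lCo to the lingual-tuberosity plane
=========================  ===================================================

Before measuring, the scan is oriented into a canonical frame (x left→right,
y posterior→anterior, z inferior→superior) defined by three user-picked
point triplets on the most external slices of the axial, coronal and
sagittal views. Orientation matters exactly insofar as it fixes the axial
and coronal planes that the construction rules reference; the
:class:`OrientationFrame` makes that dependence explicit.

Landmark coordinates must already be millimetres in scanner space; voxel
indices must be converted upstream (multiply by voxel spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteLandmarkSetError, NonOrthogonalSetupError
from .geometry import (
    Plane3,
    Point3,
    RigidTransform3,
    plane_from_three_points,
    plane_from_two_points_normal,
    plane_parallel_through_point,
    point_plane_distance,
)

__all__ = [
    "REQUIRED_LANDMARKS_3D",
    "BILATERAL_PAIRS_3D",
    "LandmarkSet3D",
    "OrientationFrame",
    "MeasurementSet3D",
    "build_orientation_frame",
    "apply_frame",
    "construct_measurement_planes",
    "measure_3d",
    "analyze_3d",
]

REQUIRED_LANDMARKS_3D = (
    "Ba", "rCo", "lCo", "rLT", "lLT", "A", "B", "SPr", "IPr", "PNS",
    "r_clinoid", "l_clinoid",
)

#: right-side name -> left-side name for the bilateral landmarks
BILATERAL_PAIRS_3D = {"rCo": "lCo", "rLT": "lLT", "r_clinoid": "l_clinoid"}

#: minimum axial/coronal normal separation before the setup counts as
#: non-orthogonal (degrees)
MIN_AXIAL_CORONAL_ANGLE_DEG = 10.0


def laterality_of(name: str) -> str:
    """'right', 'left' or 'midline' from the landmark naming convention."""
    if name in BILATERAL_PAIRS_3D:
        return "right"
    if name in BILATERAL_PAIRS_3D.values():
        return "left"
    return "midline"


@dataclass
class LandmarkSet3D:
    """Named CBCT landmarks for one subject (mm, scanner or canonical frame)."""

    subject: str
    points: dict[str, Point3] = field(default_factory=dict)
    unit: str = "mm"

    def __getitem__(self, name: str) -> Point3:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def missing(self) -> list[str]:
        return [n for n in REQUIRED_LANDMARKS_3D if n not in self.points]

    def validate(self) -> None:
        missing = self.missing()
        if missing:
            raise IncompleteLandmarkSetError(missing, "3D")

    def transformed(self, fn) -> "LandmarkSet3D":
        return LandmarkSet3D(
            subject=self.subject,
            points={k: fn(v) for k, v in self.points.items()},
            unit=self.unit,
        )


@dataclass(frozen=True)
class OrientationFrame:
    """Rigid map from scanner coordinates to the canonical frame.

    ``rotation`` (3×3, det +1) and ``translation`` apply as p ↦ R p + t.
    ``axial``/``coronal``/``sagittal`` are the canonical planes expressed in
    TARGET coordinates: z = 0, y = 0 and x = 0 respectively.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("orientation rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("orientation rotation must have determinant +1")

    @property
    def axial(self) -> Plane3:
        return Plane3(Point3(0, 0, 0), (0.0, 0.0, 1.0), provenance="canonical")

    @property
    def coronal(self) -> Plane3:
        return Plane3(Point3(0, 0, 0), (0.0, 1.0, 0.0), provenance="canonical")

    @property
    def sagittal(self) -> Plane3:
        return Plane3(Point3(0, 0, 0), (1.0, 0.0, 0.0), provenance="canonical")

    def transform(self) -> RigidTransform3:
        return RigidTransform3(self.rotation, self.translation)

    @staticmethod
    def identity() -> "OrientationFrame":
        return OrientationFrame(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class MeasurementSet3D:
    """The 3D horizontal lengths (mm, non-negative); ramus carried per side."""

    maxillary_skeletal: float
    mandibular_skeletal: float
    maxillary_dental: float
    mandibular_dental: float
    mcf: float
    ramus_right: float
    ramus_left: float

    def as_dict(self) -> dict[str, float]:
        return {
            "maxillary_skeletal": self.maxillary_skeletal,
            "mandibular_skeletal": self.mandibular_skeletal,
            "maxillary_dental": self.maxillary_dental,
            "mandibular_dental": self.mandibular_dental,
            "mcf": self.mcf,
            "ramus_right": self.ramus_right,
            "ramus_left": self.ramus_left,
        }

    def ramus(self, side: str = "right") -> float:
        if side == "right":
            return self.ramus_right
        if side == "left":
            return self.ramus_left
        if side == "mean":
            return 0.5 * (self.ramus_right + self.ramus_left)
        raise ValueError(f"unknown ramus side {side!r}")


def build_orientation_frame(axial_pts, coronal_pts, sagittal_pts) -> OrientationFrame:
    """Orientation frame from three picked point triplets, one per view.

    Each argument is a sequence of three non-collinear :class:`Point3` in
    scanner coordinates. The triplet winding (right-hand rule) fixes each
    axis sense: the axial triplet's normal becomes +z (superior), the
    coronal triplet's normal +y (anterior). The axial normal is honoured
    exactly; the coronal normal is orthogonalized against it; x is always
    y × z so the rotation is proper (det +1) even when the sagittal triplet
    winding disagrees. The canonical origin is the intersection point of
    the three picked planes.
    """
    axial = plane_from_three_points(*axial_pts, names=("axial triplet",))
    coronal = plane_from_three_points(*coronal_pts, names=("coronal triplet",))
    sagittal = plane_from_three_points(*sagittal_pts, names=("sagittal triplet",))

    z = axial.n
    cos_sep = abs(float(z @ coronal.n))
    if cos_sep > np.cos(np.deg2rad(MIN_AXIAL_CORONAL_ANGLE_DEG)):
        angle = float(np.degrees(np.arccos(np.clip(cos_sep, -1, 1))))
        raise NonOrthogonalSetupError(
            "axial and coronal orientation planes are nearly parallel "
            f"(separation {angle:.2f} deg < {MIN_AXIAL_CORONAL_ANGLE_DEG} deg)")
    y = coronal.n - (coronal.n @ z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)

    R = np.vstack([x, y, z])
    # origin: the unique point on all three (orthogonalized) planes; solving
    # R p0 = offsets places each picked plane through the target origin.
    offsets = np.array([
        x @ sagittal.anchor.as_array(),
        y @ coronal.anchor.as_array(),
        z @ axial.anchor.as_array(),
    ])
    p0 = R.T @ offsets  # R is orthonormal
    return OrientationFrame(rotation=R, translation=-R @ p0)


def apply_frame(lm: LandmarkSet3D, frame: OrientationFrame) -> LandmarkSet3D:
    """Rigidly map every landmark into the canonical frame."""
    t = frame.transform()
    return lm.transformed(t.apply)


def construct_measurement_planes(
    lm: LandmarkSet3D, frame: OrientationFrame | None = None,
) -> tuple[Plane3, Plane3, Plane3]:
    """The three measurement planes (PNS, lingual-tuberosity, clinoid).

    ``lm`` must already be in the canonical frame (i.e. after
    :func:`apply_frame`); ``frame`` only supplies the canonical axial and
    coronal planes and defaults to the identity frame.
    """
    lm.validate()
    frame = frame or OrientationFrame.identity()
    pns_plane = plane_parallel_through_point(lm["PNS"], frame.coronal)
    lt_plane = plane_from_two_points_normal(
        lm["rLT"], lm["lLT"], frame.axial, names=("rLT", "lLT"))
    clinoid_plane = plane_from_two_points_normal(
        lm["r_clinoid"], lm["l_clinoid"], frame.axial,
        names=("r_clinoid", "l_clinoid"))
    return pns_plane, lt_plane, clinoid_plane


def measure_3d(
    lm: LandmarkSet3D,
    planes: tuple[Plane3, Plane3, Plane3],
    signed: bool = False,
) -> MeasurementSet3D:
    """Point-to-plane measurements of the 3D horizontal analysis.

    Unsigned distances by default; the signed variant (using each plane's
    stored normal orientation) helps debug anterior/posterior placement
    errors but is not part of the standard report.
    """
    pns_plane, lt_plane, clinoid_plane = planes
    d = point_plane_distance
    return MeasurementSet3D(
        maxillary_skeletal=d(lm["A"], pns_plane, signed=signed),
        mandibular_skeletal=d(lm["B"], lt_plane, signed=signed),
        maxillary_dental=d(lm["SPr"], pns_plane, signed=signed),
        mandibular_dental=d(lm["IPr"], lt_plane, signed=signed),
        mcf=d(lm["Ba"], clinoid_plane, signed=signed),
        ramus_right=d(lm["rCo"], lt_plane, signed=signed),
        ramus_left=d(lm["lCo"], lt_plane, signed=signed),
    )


def analyze_3d(
    lm: LandmarkSet3D, frame: OrientationFrame | None = None,
) -> tuple[tuple[Plane3, Plane3, Plane3], MeasurementSet3D]:
    """Orient (if a frame is given), construct planes, measure."""
    if frame is not None:
        lm = apply_frame(lm, frame)
    planes = construct_measurement_planes(lm, OrientationFrame.identity())
    return planes, measure_3d(lm, planes)
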