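"""2D simplified Enlow horizontal counterpart analysis on lateral cephalograms.

The analysis takes named landmarks from a lateral cephalogram, constructs
the reference frame of the horizontal counterpart analysis — the functional
occlusal plane (FOP, Poc–Aoc), the Ref line (parallel to the FOP through
articulare Ar), the pterygo-mandibular line (PM, SE–PTM), the posterior and
anterior ramus alignments (PRa, ARa), and the constructed gonion — and then
measures six horizontal lengths along Ref:

========================  =====================================================
maxillary skeletal arch   A point to PM∩Ref, in parallel with Ref
mandibular skeletal arch  projection of B onto Ref to ARa∩Ref
maxillary dental arch     SPr to PM∩Ref, in parallel with Ref
mandibular dental arch    projection of IPr onto Ref to ARa∩Ref
middle cranial floor      Ar to PM∩Ref, along Ref
mandibular ramus          Ar to ARa∩Ref, along Ref
========================  =====================================================

"In parallel with Ref" distances reduce to absolute differences of scalar
projections onto Ref's direction, so every measurement is the along-Ref
separation of its two defining points. Signs are discarded here; they enter
only at the discrepancy (part − counterpart) stage.

Because ramus and corpus outlines are not available to a coordinate-based
tool, the three tangent/intersection points that Enlow reads off the film —
the lower-most corpus point, the posterior-most ramus point, and the point
where the FOP meets the posterior ramus margin — are required input
landmarks (``corpus_lowest``, ``ramus_posterior_most``, ``pra_fop_point``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IncompleteLandmarkSetError
from .geometry import (
    Line2,
    Point2,
    intersect_lines,
    line_parallel_through,
    line_through,
    project_point_onto_line,
)

__all__ = [
    "REQUIRED_LANDMARKS_2D",
    "LANDMARK_DESCRIPTIONS_2D",
    "LandmarkSet2D",
    "Ceph2DFrame",
    "MeasurementSet2D",
    "construct_frame",
    "measure_2d",
    "analyze_2d",
]

#: Landmarks a full 2D horizontal analysis needs.
REQUIRED_LANDMARKS_2D = (
    "Ar", "Me", "SE", "PTM", "Poc", "Aoc", "A", "SPr", "IPr", "B", "LT",
    "corpus_lowest", "ramus_posterior_most", "pra_fop_point",
)

LANDMARK_DESCRIPTIONS_2D = {
    "Ar": "Articulare: posterior ramus margin meets the cranial base outline",
    "Me": "Menton: most inferior point of the mandibular symphysis",
    "SE": "Sphenoethmoidal junction (averaged right/left shadows)",
    "PTM": "Lowest point of the pterygomaxillary fissure contour",
    "Poc": "Posterior occlusal contact (first molars)",
    "Aoc": "Anterior occlusal contact (first premolars / deciduous molars)",
    "A": "Most concave point of the anterior maxilla",
    "SPr": "Superior prosthion: occlusal limit of the maxillary alveolar papilla",
    "IPr": "Inferior prosthion: occlusal limit of the mandibular alveolar papilla",
    "B": "Most concave point of the mandibular symphysis",
    "LT": "Lingual tuberosity: FOP meets the anterior ramus border",
    "corpus_lowest": "Lower-most point of the mandibular corpus (Go tangent)",
    "ramus_posterior_most": "Posterior-most point of the ramus (Go tangent)",
    "pra_fop_point": "Point where the FOP intersects the posterior ramus margin",
}


@dataclass
class LandmarkSet2D:
    """Named lateral-cephalogram landmarks for one subject (mm).

    ``scale`` is an optional source-image scale factor (e.g. cephalostat
    magnification); when given it is applied once at load time by the I/O
    layer, so coordinates held here are always true millimetres.
    """

    subject: str
    points: dict[str, Point2] = field(default_factory=dict)
    unit: str = "mm"

    def __getitem__(self, name: str) -> Point2:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def missing(self) -> list[str]:
        return [n for n in REQUIRED_LANDMARKS_2D if n not in self.points]

    def validate(self) -> None:
        missing = self.missing()
        if missing:
            raise IncompleteLandmarkSetError(missing, "2D")

    def transformed(self, fn) -> "LandmarkSet2D":
        """New set with ``fn: Point2 -> Point2`` applied to every landmark."""
        return LandmarkSet2D(
            subject=self.subject,
            points={k: fn(v) for k, v in self.points.items()},
            unit=self.unit,
        )


@dataclass(frozen=True)
class Ceph2DFrame:
    """Constructed lines and points of the 2D horizontal analysis."""

    fop: Line2
    ref: Line2
    pm_line: Line2
    pra: Line2
    ara: Line2
    go: Point2          # constructed gonion; diagnostic only
    pm_ref: Point2      # PM ∩ Ref ("neutral PM" on the Ref line)
    ara_ref: Point2     # ARa ∩ Ref


@dataclass(frozen=True)
class MeasurementSet2D:
    """The six horizontal lengths of the 2D analysis (mm, non-negative)."""

    maxillary_skeletal: float
    mandibular_skeletal: float
    maxillary_dental: float
    mandibular_dental: float
    mcf: float
    ramus: float

    def as_dict(self) -> dict[str, float]:
        return {
            "maxillary_skeletal": self.maxillary_skeletal,
            "mandibular_skeletal": self.mandibular_skeletal,
            "maxillary_dental": self.maxillary_dental,
            "mandibular_dental": self.mandibular_dental,
            "mcf": self.mcf,
            "ramus": self.ramus,
        }


def construct_frame(lm: LandmarkSet2D) -> Ceph2DFrame:
    """Build the constructed lines/points of the horizontal analysis.

    Raises :class:`~enlowcp.errors.IncompleteLandmarkSetError` when required
    landmarks are missing and :class:`~enlowcp.errors.DegenerateGeometryError`
    (naming the landmarks involved) for singular constructions such as a PM
    line parallel to Ref.
    """
    lm.validate()
    fop = line_through(lm["Poc"], lm["Aoc"], names=("Poc", "Aoc"))
    ref = line_parallel_through(lm["Ar"], fop)
    pm_line = line_through(lm["SE"], lm["PTM"], names=("SE", "PTM"))
    pra = line_through(lm["Ar"], lm["pra_fop_point"],
                       names=("Ar", "pra_fop_point"))
    ara = line_parallel_through(lm["LT"], pra)

    # Constructed gonion: corpus tangent (Me -> lowest corpus point) meets
    # ramus tangent (Ar -> posterior-most ramus point). Not used by any
    # horizontal measurement; emitted as a diagnostic aid.
    corpus_tangent = line_through(lm["Me"], lm["corpus_lowest"],
                                  names=("Me", "corpus_lowest"))
    ramus_tangent = line_through(lm["Ar"], lm["ramus_posterior_most"],
                                 names=("Ar", "ramus_posterior_most"))
    go = intersect_lines(corpus_tangent, ramus_tangent,
                         names=("Me-corpus tangent", "Ar-ramus tangent"))

    pm_ref = intersect_lines(pm_line, ref, names=("PM line", "Ref"))
    ara_ref = intersect_lines(ara, ref, names=("ARa", "Ref"))
    return Ceph2DFrame(fop=fop, ref=ref, pm_line=pm_line, pra=pra, ara=ara,
                       go=go, pm_ref=pm_ref, ara_ref=ara_ref)


def measure_2d(lm: LandmarkSet2D, frame: Ceph2DFrame) -> MeasurementSet2D:
    """Measure the six horizontal lengths along the Ref line."""
    ref = frame.ref
    s = ref.coordinate_of  # scalar along-Ref position

    s_pm = s(frame.pm_ref)
    s_ara = s(frame.ara_ref)
    s_ar = s(lm["Ar"])
    # projections onto Ref keep the along-Ref coordinate, so projecting B /
    # IPr first (as the analysis prescribes) is already folded into s().
    return MeasurementSet2D(
        maxillary_skeletal=abs(s(lm["A"]) - s_pm),
        mandibular_skeletal=abs(s(project_point_onto_line(lm["B"], ref)) - s_ara),
        maxillary_dental=abs(s(lm["SPr"]) - s_pm),
        mandibular_dental=abs(s(project_point_onto_line(lm["IPr"], ref)) - s_ara),
        mcf=abs(s_ar - s_pm),
        ramus=abs(s_ar - s_ara),
    )


def analyze_2d(lm: LandmarkSet2D) -> tuple[Ceph2DFrame, MeasurementSet2D]:
    """Convenience: construct the frame and measure in one call."""
    frame = construct_frame(lm)
    return frame, measure_2d(lm, frame)
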