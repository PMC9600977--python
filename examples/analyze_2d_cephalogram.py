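"""2D horizontal counterpart analysis of one lateral cephalogram.

Builds a small landmark set (coordinates in mm, x posterior→anterior,
y inferior→superior), constructs the analysis frame (FOP, Ref, PM line,
ramus alignments, gonion) and prints the six horizontal lengths and the
three part-counterpart discrepancies with their harmony labels.
"""

from enlowcp import LandmarkSet2D, analyze_2d, discrepancies
from enlowcp.geometry import Point2

landmarks = LandmarkSet2D("demo-2d", {
    name: Point2(*xy) for name, xy in {
        "Poc": (10, 0), "Aoc": (30, 0), "Ar": (-25, 40), "SE": (0, 50),
        "PTM": (5, 10), "LT": (0, 0), "pra_fop_point": (-15, 0),
        "A": (45, 25), "B": (42, -15), "SPr": (48, 15), "IPr": (46, -5),
        "Me": (40, -20), "corpus_lowest": (20, -22),
        "ramus_posterior_most": (-22, 20),
    }.items()
})

frame, measurements = analyze_2d(landmarks)

print("constructed points on the Ref line:")
print(f"  PM ∩ Ref  = ({frame.pm_ref.x:.2f}, {frame.pm_ref.y:.2f})")
print(f"  ARa ∩ Ref = ({frame.ara_ref.x:.2f}, {frame.ara_ref.y:.2f})")
print(f"  gonion    = ({frame.go.x:.2f}, {frame.go.y:.2f})  (diagnostic)")

print("\nhorizontal lengths along Ref (mm):")
for name, value in measurements.as_dict().items():
    print(f"  {name:<20s} {value:7.2f}")

report = discrepancies(measurements, subject=landmarks.subject)
print("\npart − counterpart discrepancies (mm):")
for index in ("mcf_ramus", "skeletal_arches", "dental_arches"):
    print(f"  {index:<16s} {report.value(index):+7.2f}  {report.harmony[index]}")

# A discrepancy within ±2.5 mm means the part and its counterpart are in
# harmonic balance; larger magnitudes flag a skeletal imbalance along that
# dimension (sign: + part longer, − counterpart longer).
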