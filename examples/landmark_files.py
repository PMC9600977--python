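"""Reading and writing landmark files (CSV, JSON, 3D Slicer FCSV).

Writes a synthetic subject's 3D landmarks as an FCSV fiducial file and as
CSV, reads them back, and shows that an LPS-coordinate FCSV yields the same
measurements as its RAS twin once the sign convention is applied.
"""

import tempfile
from pathlib import Path

from enlowcp import analyze_3d, generate_skull, read_landmarks, write_landmarks
from enlowcp.synthetic import SkullConfig

skull = generate_skull(SkullConfig(noise_sd=0.0), subject="demo")
workdir = Path(tempfile.mkdtemp())

fcsv = write_landmarks(skull.lm3d, workdir / "demo.fcsv")
csvf = write_landmarks(skull.lm3d, workdir / "demo.csv")
print("wrote:", fcsv.name, "and", csvf.name)
print("FCSV header lines:")
for line in fcsv.read_text().splitlines()[:3]:
    print("  ", line)

back = read_landmarks(fcsv)
_, m_fcsv = analyze_3d(back)
_, m_csv = analyze_3d(read_landmarks(csvf))
assert m_fcsv.as_dict() == m_csv.as_dict()

# fabricate the LPS twin of the same anatomy: Slicer files in the wild use
# either convention, flagged in the CoordinateSystem header
lps = workdir / "demo_lps.fcsv"
lines = []
for line in fcsv.read_text().splitlines():
    if line.startswith("#"):
        lines.append(line.replace("CoordinateSystem = RAS",
                                  "CoordinateSystem = LPS"))
    else:
        f = line.split(",")
        f[1], f[2] = repr(-float(f[1])), repr(-float(f[2]))
        lines.append(",".join(f))
lps.write_text("\n".join(lines) + "\n")

_, m_lps = analyze_3d(read_landmarks(lps))
print("\nmeasurements from RAS and LPS files (mm):")
for name in ("maxillary_skeletal", "mcf", "ramus_right"):
    print(f"  {name:<20s} RAS {m_fcsv.as_dict()[name]:7.3f}"
          f"   LPS {m_lps.as_dict()[name]:7.3f}")
# identical numbers: the reader converts LPS to the canonical (RAS-like)
# frame, so the downstream analysis never sees the file-level convention
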