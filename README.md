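# enlowcp — Enlow counterpart analysis on 2D and 3D cephalometric landmarks

`enlowcp` is a toolkit for orthodontic and maxillofacial researchers who
work with craniofacial landmark coordinates. It implements Enlow's
**horizontal counterpart analysis** — the comparison of each craniofacial
"part" with its structural "counterpart" by the millimeter difference
method — in two forms:

* the **classical 2D form** on lateral-cephalogram landmarks, where the
  lengths are measured along the Ref line (parallel to the functional
  occlusal plane through articulare) between constructed points such as
  PM ∩ Ref and ARa ∩ Ref; and
* a **3D form** on CBCT landmark coordinates, where every length is an
  unsigned point-to-plane distance against anatomically defined planes:
  the PNS plane (through the posterior nasal spine, parallel to the
  coronal plane), the lingual-tuberosity plane and the anterior-clinoid
  plane (each through a bilateral landmark pair, perpendicular to the
  axial plane).

Three indices are scored in both forms, as part − counterpart (mm):

| index | part | counterpart |
|---|---|---|
| MCF − ramus | middle cranial floor | mandibular ramus (right, by convention, in 3D) |
| skeletal arches | maxillary skeletal arch | mandibular skeletal arch |
| dental arches | maxillary dento-alveolar arch | mandibular dento-alveolar arch |

A difference of magnitude 0–2.5 mm (inclusive) is classified *harmonic* —
Enlow's ideal, balanced configuration. Paired 2D/3D cohorts can be compared
statistically (Kolmogorov–Smirnov normality check, paired Student's
t-test), and a seeded synthetic skull generator with planted ground-truth
lengths provides a validation bed, since clinical CBCT landmark datasets
are rarely shareable.

Landmark identification is upstream of this package: inputs are named
coordinate sets (CSV, JSON, or 3D Slicer FCSV fiducial files, RAS/LPS
aware), never DICOM volumes.

## Worked example

```python
from enlowcp import LandmarkSet3D, analyze_3d, discrepancies
from enlowcp.geometry import Point3

lm = LandmarkSet3D("subject-01", {name: Point3(*xyz) for name, xyz in {
    "PNS": (0, -10, 0), "rLT": (20, -15, -10), "lLT": (-20, -15, -10),
    "r_clinoid": (12, 5, 20), "l_clinoid": (-12, 5, 20),
    "A": (0, 35, -5), "B": (0, 33, -25), "SPr": (0, 38, -8),
    "IPr": (0, 36, -22), "Ba": (0, -22, 12),
    "rCo": (45, -40, 5), "lCo": (-45, -40, 5)}.items()})

planes, m = analyze_3d(lm)
print(m.as_dict())
report = discrepancies(m, subject=lm.subject)
print(report.mcf_ramus, report.harmony["mcf_ramus"])
```

prints

```
{'maxillary_skeletal': 45.0, 'mandibular_skeletal': 48.0,
 'maxillary_dental': 48.0, 'mandibular_dental': 51.0,
 'mcf': 27.0, 'ramus_right': 25.0, 'ramus_left': 25.0}
2.0 harmonic
```

i.e. point A sits 45 mm anterior to the PNS plane while B is 48 mm anterior
to the lingual-tuberosity plane (a 3 mm mandibular excess, non-harmonic),
and the middle cranial floor exceeds the right ramus by 2 mm, inside the
harmonic 0–2.5 mm band.

The `examples/` directory holds one short script per capability: the 2D
analysis with its constructed frame, the 3D analysis including scan
orientation from picked point triplets, the synthetic paired-cohort study,
and landmark-file handling (CSV/JSON/FCSV, RAS vs LPS). A cohort run prints
a comparison table like

```
          index   mean_2d_cm  sd_2d_cm  mean_3d_cm  sd_3d_cm  ks_p_2d  ks_p_3d  paired_t_p
      mcf_ramus        0.224     0.474       0.214     0.443    0.989    0.828       0.811
skeletal_arches       -0.464     0.316      -0.452     0.262    0.956    0.951       0.813
  dental_arches       -0.431     0.203      -0.415     0.263    0.853    0.868       0.733
```

where matching 2D/3D means and p-values above 0.05 show the two analyses
agree on matched geometry.

A thin CLI wraps the same API:

```bash
enlowcp simulate --n 18 --seed 1 --out cohort/
enlowcp analyze3d cohort/S001_3d.json --report S001_3d_report.json
enlowcp analyze2d cohort/S001_2d.json --report S001_2d_report.json
enlowcp compare *_report.json --units cm --out table.csv
```

## Layout

- `src/enlowcp/geometry.py` — 2D/3D primitives and the three plane-construction rules
- `src/enlowcp/ceph2d.py` — lateral-cephalogram frame construction and measurement
- `src/enlowcp/ceph3d.py` — orientation frame, measurement planes, 3D measurement
- `src/enlowcp/counterpart.py` — discrepancies, harmony, cohort statistics
- `src/enlowcp/synthetic.py` — seeded skull generator and lateral projection
- `src/enlowcp/io.py`, `src/enlowcp/cli.py` — file formats, reports, CLI
- `docs/methods.md` — the scientific and numerical design of the package
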