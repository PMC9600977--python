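# Methods

## The counterpart model

Enlow's counterpart analysis treats the face as a set of paired structural
units: the horizontal dimension of each "part" (maxillary skeletal arch,
maxillary dento-alveolar arch, middle cranial floor) is compared with its
"counterpart" (mandibular skeletal arch, mandibular dento-alveolar arch,
mandibular ramus) by simple subtraction. Facial balance does not require
any unit to match a population norm — only that each part and its
counterpart offset each other. The millimeter difference method classifies
a part − counterpart difference `d` as *harmonic* when `|d| ≤ 2.5 mm`
(boundary inclusive; the threshold is a configuration knob with 2.5 mm
default) and *non-harmonic* otherwise. Each subject is compared with
themselves, never with population averages.

### 2D form (lateral cephalogram)

All six lengths are measured along the **Ref** line — parallel to the
functional occlusal plane (FOP, Poc–Aoc) through articulare (Ar):

* maxillary skeletal arch: A to PM ∩ Ref, in parallel with Ref;
* mandibular skeletal arch: orthogonal projection of B on Ref to ARa ∩ Ref;
* maxillary dental arch: SPr to PM ∩ Ref; mandibular dental arch:
  projection of IPr on Ref to ARa ∩ Ref;
* middle cranial floor: Ar to PM ∩ Ref; ramus: Ar to ARa ∩ Ref.

"In parallel with Ref" distances are computed as absolute differences of
scalar projections onto Ref's direction, so each measurement depends on a
landmark only through its along-Ref coordinate; anterior-posterior sign is
discarded at the measurement level and re-enters only in the discrepancy
subtraction. Two interpretation choices were genuinely open:

* **"Neutral PM"** is taken as the intersection of the PM line (SE–PTM)
  with Ref, so the MCF length is the along-Ref separation of Ar and
  PM ∩ Ref. Both MCF and ramus are explicitly along-Ref quantities and
  PM ∩ Ref is the only PM-derived point available on that line; a rotated
  "neutral vertical PM" construct would need vertical-analysis machinery
  that is out of scope here.
* **Mandibular lengths** use ARa ∩ Ref (not the LT projection directly),
  following the same along-Ref logic.

Because a coordinate-based tool has no access to the ramus/corpus outlines,
the three outline-tangent constructs are required *input* landmarks:
`pra_fop_point` (FOP meets the posterior ramus margin, anchoring PRa),
`corpus_lowest` and `ramus_posterior_most` (the two tangent points of the
constructed gonion). Gonion itself is constructed and reported as a
diagnostic but feeds no horizontal measurement. An optional source-image
scale factor is applied once at load time.

### 3D form (CBCT landmarks)

The 3D analysis uses purely anatomical landmarks and exactly three plane
construction rules: through three points; through two points perpendicular
to a reference plane; through one point parallel to a reference plane.
The measurement planes are

* the **PNS plane**: through the posterior nasal spine, parallel to the
  coronal plane (maxillary targets A, SPr);
* the **lingual-tuberosity plane**: through right and left lingual
  tuberosity (the retromolar-triangle apices), perpendicular to the axial
  plane — it splits the mandible into corpus and ramus (mandibular targets
  B, IPr; ramus sources rCo, lCo);
* the **clinoid plane**: through the two anterior clinoid processes,
  perpendicular to the axial plane — the anterior/middle cranial floor
  boundary (MCF source: basion).

All lengths are unsigned point-to-plane distances (the analysis reports
lengths; signed variants exist for debugging anterior/posterior placement
errors). Both rami are always computed; the right one feeds the MCF − ramus
discrepancy by convention, switchable to left or the mean of sides.

**Orientation.** Scans are first oriented into a canonical frame
(x left→right, y posterior→anterior, z inferior→superior) defined by three
user-picked point triplets on the outer axial, coronal and sagittal slices.
The triplet winding (right-hand rule) fixes each axis sense. When the
picked planes are not mutually orthogonal, the axial normal is honoured
exactly (both "perpendicular to the axial plane" constructions reference
it), the coronal normal is orthogonalized against it, and the mediolateral
axis is taken as their cross product so the rotation is always proper
(det +1) — a sagittal triplet disagreeing with the handedness of the other
two is overridden rather than producing a reflection. Axial/coronal
triplets whose normals are within 10° of parallel are rejected as a
non-orthogonal setup. The canonical origin is the intersection point of the
three picked planes; measurements are invariant to it. Landmark coordinates
must already be millimetres in scanner space (voxel indices are converted
upstream); the literal two-point-plus-normal construction is used for the
bilateral planes, with no additional constraint forcing them parallel to
the coronal plane.

## Geometry and numerics

Lines are stored as anchor + unit direction (no slope/intercept, so
vertical lines need no special case); planes as anchor + unit normal plus a
provenance tag naming the construction rule. Three-point plane normals
follow the right-hand rule over (p2−p1)×(p3−p1) so signed distances are
reproducible from point order. Degeneracy tolerances are 1e-9 mm for point
coincidence/containment and 1e-6 rad for parallelism, adjustable through a
single module-level tolerance object; degenerate constructions raise errors
that name the offending landmarks. All computation is in mm; unit
conversion (cm display, cm-unit input files) is confined to the I/O layer.

## Statistics

The 2D-vs-3D cohort comparison mirrors a paired study design: per-index
mean ± SD per modality (n−1 SD), a Kolmogorov–Smirnov normality check per
variable, and a two-sided **paired** Student's t-test per index at
α = 0.05. The paired test is the default because both analyses measure the
same subject; an unpaired (equal-variance) variant is available for
sensitivity analysis. The KS test is the classical variant against a normal
with sample-estimated mean and SD, with p from the asymptotic KS
distribution; estimating the parameters from the same sample makes it
anti-conservative, so a Lilliefors-corrected p-value (via statsmodels) is
offered as an option, off by default to mirror common clinical usage.
Degenerate situations (zero-variance paired differences, constant samples)
raise a dedicated error, which the cohort table surfaces per index instead
of aborting. No multiple-testing correction is applied across the three
indices.

## Synthetic skull generator

The generator is the validation bed standing in for clinical CBCT cohorts.
It emulates a skeletal Class I configuration as named landmark coordinates
only — no images, no growth modelling.

**Construction.** Bilateral landmark pairs (lingual tuberosities, clinoid
processes, condyles) are placed first, symmetric about the sagittal plane
up to configurable anteroposterior asymmetry offsets. The measurement
planes implied by those pairs are computed, and the midline landmarks
(A, SPr, B, IPr, Ba) plus the condyles are then dropped at the planted
lengths *along the plane normals*, so each planted 3D length is realized
exactly by the actual plane constructions — including under asymmetry,
where the lingual-tuberosity plane tilts but still contains both LT points.
The matched 2D set is an orthographic lateral projection (the mediolateral
axis is dropped; bilateral pairs collapse to their midpoint, the "averaged
shadow" of film cephalometry), with a single uniform magnification knob and
no perspective model. 2D-only constructs (occlusal contacts, SE, PTM,
articulare, gonion tangents) are template points tied to the 3D geometry:
the PM line is laid through the point of Ref above the PNS, the posterior
ramus alignment is vertical below articulare, and the PNS anterior offset
equals (mcf − ramus_right) — these three choices make all six 2D lengths
equal the planted 3D lengths exactly for symmetric noise-free skulls.
Asymmetry shifts the midline shadows and consumes part of a 0.5 mm 2D/3D
design tolerance, which is a template constant, not a measurement property.

**Defaults.** Planted lengths (mm): maxillary skeletal 50.0 / mandibular
55.4, maxillary dental 50.0 / mandibular 54.7, MCF 31.7 / ramus 30.0 —
plausible late-adolescent magnitudes whose three discrepancies (−5.4, −4.7,
+1.7 mm) represent a mild mandibular excess with a harmonic MCF-ramus
relation. Between-subject variation draws each planted length from
N(base, 2.3 mm); landmark placement noise is isotropic Gaussian with
SD 0.5 mm per coordinate, drawn independently for the 2D and 3D sets
because the two tracings are performed independently. The noise SD is an
assumed operator-error magnitude, not a measured one. Cohorts are a
deterministic function of (config, seed).

**What passing tests do and do not show.** The generator plants geometry
that the pipelines can recover exactly, so recovery tests validate the
construction algebra, projection logic and statistical plumbing — they do
not validate landmark identifiability on real images, real anatomical shape
variation (outlines, curvature, oblique occlusal planes), or perspective/
magnification artifacts of real cephalostats. The synthetic 2D/3D
equivalence study shows the *method* introduces no systematic 2D-vs-3D
bias under matched geometry; it cannot show that real 2D and 3D tracings
agree, which depends on operator error structure the generator only
caricatures.

## Validation suite problem sizes

The test and acceptance runs use: 1000 random instances for the geometry
oracles (point-to-plane distance vs a coarse-to-fine dense-sampling
minimizer; construction contracts at 1e-9), 100 noise-free skulls for
parameter recovery (1e-6 mm), 100 random rigid motions for invariance
(1e-9 mm), and 100 replicate cohorts of n = 18 with 0.5 mm noise for the
equivalence study, asserting each index stays non-significant (p > 0.05)
in at least 90 of 100 cohorts — per index, the statistically well-posed
form of the property, since each test sits at its nominal 5% level under
the matched template.

## Known limitations

* The 2D analysis requires the outline-derived tangent points as inputs;
  films annotated without them cannot be processed.
* The lingual-tuberosity plane uses the literal two-point construction;
  strongly asymmetric mandibles yield an oblique plane whose distances mix
  anteroposterior and mediolateral components.
* The classical KS normality test is anti-conservative at small n; prefer
  the Lilliefors option when the normality decision matters.
* No vertical counterpart or neutral-track analysis; horizontal only.
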