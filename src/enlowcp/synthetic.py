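"""Seeded synthetic skull-landmark generator with planted counterpart lengths.

The generator builds ground-truth 3D landmark configurations in the
canonical frame so that every planted part/counterpart length is realized
*exactly* by the 3D plane constructions: the PNS plane, the
lingual-tuberosity plane and the clinoid plane are built first from the
placed bilateral landmarks, then A/B/SPr/IPr/Ba and the condyles are
dropped at the planted distances along the plane normals. A matched 2D
lateral-cephalogram landmark set is produced by orthographic projection
(bilateral pairs collapse to their midpoint shadow, as on a film), with the
2D-only constructs — occlusal contacts, SE, PTM, articulare, the gonion
tangent points — placed consistently so the 2D frame reproduces the same
planted lengths for symmetric skulls.

Two template choices make 2D and 3D agree for symmetric, noise-free skulls:
the PM line is laid through the point of Ref directly above the PNS, and
the PNS anterior offset is tied to (mcf − ramus_right) so the articulare-
based 2D middle cranial floor equals the clinoid-based 3D one. Bilateral
asymmetry tilts the midline shadows and consumes a small (≤ 0.5 mm by
design) 2D/3D mismatch; that tolerance is a template constant, not a
measurement property.

Default planted lengths emulate a skeletal Class I configuration: all three
part-counterpart discrepancies fall in or near the 0–2.5 mm harmonic band
apart from a mild maxillary-mandibular excess typical of growing subjects.
Landmark-placement noise is isotropic Gaussian per coordinate (default SD
0.5 mm — an assumed operator-error magnitude, not a measured one), drawn
independently for the 2D and 3D sets because the two analyses are traced
independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .ceph2d import LandmarkSet2D, MeasurementSet2D, analyze_2d
from .ceph3d import (
    BILATERAL_PAIRS_3D,
    LandmarkSet3D,
    MeasurementSet3D,
    analyze_3d,
)
from .errors import EnlowError
from .geometry import Point2, Point3

__all__ = [
    "SkullConfig",
    "SyntheticSkull",
    "generate_skull",
    "project_lateral",
    "add_landmark_noise",
    "generate_cohort",
    "CANONICAL_ORIENTATION_TRIPLETS",
]

#: Orientation-view point triplets spanning the canonical planes, wound so
#: the right-hand-rule normals point superior (+z), anterior (+y), right (+x).
CANONICAL_ORIENTATION_TRIPLETS = (
    (Point3(0, 0, 0), Point3(1, 0, 0), Point3(0, 1, 0)),   # axial, n = +z
    (Point3(0, 0, 0), Point3(0, 0, 1), Point3(1, 0, 0)),   # coronal, n = +y
    (Point3(0, 0, 0), Point3(0, 1, 0), Point3(0, 0, 1)),   # sagittal, n = +x
)

_PLANTED_FIELDS = (
    "maxillary_skeletal", "mandibular_skeletal",
    "maxillary_dental", "mandibular_dental",
    "mcf", "ramus_right", "ramus_left",
)


@dataclass(frozen=True)
class SkullConfig:
    """Parameters of one synthetic skull (all lengths mm).

    Planted lengths are the ground-truth part/counterpart dimensions the
    landmark placement realizes. Half-widths set the bilateral spread of
    paired landmarks about the sagittal plane; asymmetry offsets displace
    the right-side member anteriorly. ``length_sd`` is the between-subject
    SD applied to every planted length by :func:`generate_cohort`;
    ``noise_sd`` is the per-coordinate landmark placement noise.
    """

    # planted part/counterpart lengths
    maxillary_skeletal: float = 50.0
    mandibular_skeletal: float = 55.4
    maxillary_dental: float = 50.0
    mandibular_dental: float = 54.7
    mcf: float = 31.7
    ramus_right: float = 30.0
    ramus_left: float = 30.0
    # bilateral geometry
    lt_halfwidth: float = 30.0
    clinoid_halfwidth: float = 12.0
    condyle_halfwidth: float = 48.0
    lt_asymmetry_y: float = 0.0
    clinoid_asymmetry_y: float = 0.0
    # vertical (z) placements in the canonical frame
    pns_z: float = 0.0
    a_z: float = -5.0
    spr_z: float = -8.0
    b_z: float = -25.0
    ipr_z: float = -22.0
    lt_z: float = -10.0
    clinoid_z: float = 20.0
    ba_z: float = 12.0
    condyle_z: float = 5.0
    # anteroposterior (y) anchors
    lt_y: float = -15.0
    clinoid_y: float = 5.0
    # 2D-template constants
    se_z: float = 28.0
    ptm_z: float = -4.0
    pm_slope: float = 0.15          # PM-line anterior lean per mm of height
    ar_z_offset: float = 3.0        # articulare height above the condyles
    # stochastic settings
    noise_sd: float = 0.5
    length_sd: float = 2.3
    magnification: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in _PLANTED_FIELDS:
            if getattr(self, name) <= 0:
                raise EnlowError(f"planted length {name} must be positive")
        if self.noise_sd < 0:
            raise EnlowError("noise_sd must be non-negative")
        if self.length_sd < 0:
            raise EnlowError("length_sd must be non-negative")
        if min(self.lt_halfwidth, self.clinoid_halfwidth,
               self.condyle_halfwidth) <= 0:
            raise EnlowError("bilateral half-widths must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticSkull:
    """One generated subject: noisy landmark sets plus ground truth."""

    subject: str
    config: SkullConfig
    seed: int
    lm3d: LandmarkSet3D
    lm2d: LandmarkSet2D
    lm3d_clean: LandmarkSet3D
    lm2d_clean: LandmarkSet2D
    truth3d: MeasurementSet3D
    truth2d: MeasurementSet2D
    orientation_triplets: tuple = CANONICAL_ORIENTATION_TRIPLETS


def _horizontal_unit_normal(p_right: Point3, p_left: Point3) -> np.ndarray:
    """Anterior-pointing horizontal normal of the vertical plane through a
    bilateral pair (the direction the planted lengths are laid along)."""
    seg = p_left.as_array() - p_right.as_array()
    n = np.cross(seg, np.array([0.0, 0.0, 1.0]))
    n /= np.linalg.norm(n)
    if n[1] < 0:
        n = -n
    return n


def _build_template(cfg: SkullConfig) -> tuple[LandmarkSet3D, dict[str, Point2]]:
    """Noise-free 3D landmarks plus the auxiliary 2D-only landmark template."""
    z = np.array([0.0, 0.0, 1.0])

    # bilateral structures first: the measurement planes derive from them
    rLT = Point3(cfg.lt_halfwidth, cfg.lt_y + cfg.lt_asymmetry_y, cfg.lt_z)
    lLT = Point3(-cfg.lt_halfwidth, cfg.lt_y, cfg.lt_z)
    n_lt = _horizontal_unit_normal(rLT, lLT)
    m_lt = 0.5 * (rLT.as_array() + lLT.as_array())
    u_lt = np.cross(n_lt, z)            # in-plane, points toward the right

    r_cl = Point3(cfg.clinoid_halfwidth,
                  cfg.clinoid_y + cfg.clinoid_asymmetry_y, cfg.clinoid_z)
    l_cl = Point3(-cfg.clinoid_halfwidth, cfg.clinoid_y, cfg.clinoid_z)
    n_cl = _horizontal_unit_normal(r_cl, l_cl)
    m_cl = 0.5 * (r_cl.as_array() + l_cl.as_array())

    # PNS anterior offset tied to (mcf − ramus_right) so the 2D articulare-
    # based MCF equals the 3D clinoid-based one on symmetric skulls
    pns_y = cfg.lt_y + (cfg.mcf - cfg.ramus_right)
    pns = Point3(0.0, pns_y, cfg.pns_z)

    def drop(base: np.ndarray, normal: np.ndarray, length: float,
             lateral: float, height: float) -> Point3:
        """Point at exact unsigned distance ``length`` from the vertical
        plane through ``base`` with ``normal``; lateral/height move within
        the plane's isodistance set."""
        p = base + normal * length + np.cross(normal, z) * lateral
        p[2] = height
        return Point3.from_array(p)

    lm3d = LandmarkSet3D(subject="", points={
        "rLT": rLT, "lLT": lLT,
        "r_clinoid": r_cl, "l_clinoid": l_cl,
        "PNS": pns,
        "A": Point3(0.0, pns_y + cfg.maxillary_skeletal, cfg.a_z),
        "SPr": Point3(0.0, pns_y + cfg.maxillary_dental, cfg.spr_z),
        "B": drop(m_lt, n_lt, cfg.mandibular_skeletal, 0.0, cfg.b_z),
        "IPr": drop(m_lt, n_lt, cfg.mandibular_dental, 0.0, cfg.ipr_z),
        "Ba": drop(m_cl, -n_cl, cfg.mcf, 0.0, cfg.ba_z),
        "rCo": drop(m_lt, -n_lt, cfg.ramus_right, cfg.condyle_halfwidth,
                    cfg.condyle_z),
        "lCo": drop(m_lt, -n_lt, cfg.ramus_left, -cfg.condyle_halfwidth,
                    cfg.condyle_z),
    })

    # --- auxiliary 2D-only landmarks (lateral-film frame: x = canonical y,
    # y = canonical z) ----------------------------------------------------
    lt2d_x = float(m_lt[1])
    ar_x = lt2d_x - cfg.ramus_right
    ar_z = cfg.condyle_z + cfg.ar_z_offset
    z_occ = 0.5 * (cfg.spr_z + cfg.ipr_z)
    b2d_x = float(m_lt[1] + n_lt[1] * cfg.mandibular_skeletal)
    aux2d = {
        "Ar": Point2(ar_x, ar_z),
        "Poc": Point2(lt2d_x + 8.0, z_occ),
        "Aoc": Point2(lt2d_x + 28.0, z_occ),
        "pra_fop_point": Point2(ar_x, z_occ),
        "SE": Point2(pns_y + cfg.pm_slope * (cfg.se_z - ar_z), cfg.se_z),
        "PTM": Point2(pns_y + cfg.pm_slope * (cfg.ptm_z - ar_z), cfg.ptm_z),
        "Me": Point2(b2d_x - 3.0, cfg.b_z - 6.0),
        "corpus_lowest": Point2(b2d_x - 20.0, cfg.b_z - 7.5),
        "ramus_posterior_most": Point2(ar_x - 2.0, 0.5 * (ar_z + z_occ)),
    }
    return lm3d, aux2d


#: 3D landmarks that carry over to the lateral projection, and the 2D name
#: the projected shadow takes. Bilateral pairs collapse to their midpoint.
_PROJECTED_3D = {"A": "A", "B": "B", "SPr": "SPr", "IPr": "IPr"}
_PROJECTED_PAIRS = {("rLT", "lLT"): "LT"}


def _project3(p: Point3) -> Point2:
    # drop the mediolateral axis: canonical (x, y, z) -> film (y, z)
    return Point2(p.y, p.z)


def project_lateral(skull_or_lm, aux2d: dict[str, Point2] | None = None,
                    magnification: float = 1.0) -> LandmarkSet2D:
    """Orthographic lateral projection of a 3D landmark set.

    Accepts a :class:`SyntheticSkull` (its clean template and auxiliary 2D
    landmarks are used) or a raw :class:`LandmarkSet3D` plus an ``aux2d``
    mapping for the 2D-only landmarks. The mediolateral axis is dropped and
    bilateral pairs collapse to their midpoint projection — the "averaged
    shadow" convention of film cephalometry. ``magnification`` scales all
    projected coordinates uniformly about the origin.
    """
    if isinstance(skull_or_lm, SyntheticSkull):
        lm3d = skull_or_lm.lm3d_clean
        aux2d = _build_template(skull_or_lm.config)[1]
        magnification = skull_or_lm.config.magnification
    else:
        lm3d = skull_or_lm
        aux2d = dict(aux2d or {})

    pts: dict[str, Point2] = {}
    for name3, name2 in _PROJECTED_3D.items():
        if name3 in lm3d:
            pts[name2] = _project3(lm3d[name3])
    for (right, left), name2 in _PROJECTED_PAIRS.items():
        if right in lm3d and left in lm3d:
            mid = 0.5 * (lm3d[right].as_array() + lm3d[left].as_array())
            pts[name2] = _project3(Point3.from_array(mid))
    pts.update(aux2d)
    if magnification != 1.0:
        pts = {k: Point2(v.x * magnification, v.y * magnification)
               for k, v in pts.items()}
    return LandmarkSet2D(subject=lm3d.subject, points=pts)


def add_landmark_noise(lm, sigma: float, seed=None):
    """Independent isotropic Gaussian perturbation of every coordinate.

    ``sigma`` in mm; ``sigma = 0`` returns an identical copy. ``seed`` may
    be an int or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise EnlowError(f"noise SD must be non-negative, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0:
        return lm.transformed(lambda p: p)

    def jitter(p):
        a = p.as_array()
        return type(p).from_array(a + rng.normal(0.0, sigma, size=a.shape))

    return lm.transformed(jitter)


def generate_skull(config: SkullConfig | None = None,
                   subject: str = "synthetic",
                   rng: np.random.Generator | None = None) -> SyntheticSkull:
    """Generate one synthetic skull with ground-truth measurements.

    The noise-free template is measured through the actual 2D and 3D
    analysis pipelines to give the truth sets (for symmetric configs the 3D
    truth equals the planted lengths exactly); landmark noise is then drawn
    independently for the 3D and projected 2D sets.
    """
    cfg = config or SkullConfig()
    rng = rng or np.random.default_rng(cfg.seed)

    lm3d_clean, aux2d = _build_template(cfg)
    lm3d_clean = replace_subject(lm3d_clean, subject)
    lm2d_clean = project_lateral(lm3d_clean, aux2d,
                                 magnification=cfg.magnification)

    _, truth3d = analyze_3d(lm3d_clean)
    _, truth2d = analyze_2d(lm2d_clean)

    lm3d = add_landmark_noise(lm3d_clean, cfg.noise_sd, seed=rng)
    lm2d = add_landmark_noise(lm2d_clean, cfg.noise_sd, seed=rng)
    return SyntheticSkull(
        subject=subject, config=cfg, seed=cfg.seed,
        lm3d=lm3d, lm2d=lm2d,
        lm3d_clean=lm3d_clean, lm2d_clean=lm2d_clean,
        truth3d=truth3d, truth2d=truth2d,
    )


def replace_subject(lm, subject: str):
    out = lm.transformed(lambda p: p)
    out.subject = subject
    return out


def generate_cohort(n: int, config: SkullConfig | None = None,
                    seed: int = 0) -> list[SyntheticSkull]:
    """Generate ``n`` independent subjects.

    Each subject draws its planted lengths from N(base, ``length_sd``)
    (clipped to stay positive) and its landmark noise independently; the
    whole cohort is a deterministic function of (config, seed).
    """
    if n < 1:
        raise EnlowError(f"cohort size must be >= 1, got {n}")
    cfg = config or SkullConfig()
    master = np.random.default_rng(seed)
    skulls = []
    for i in range(n):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        draws = {}
        if cfg.length_sd > 0:
            for name in _PLANTED_FIELDS:
                base = getattr(cfg, name)
                val = sub_rng.normal(base, cfg.length_sd)
                draws[name] = float(np.clip(val, 0.2 * base, None))
        sub_cfg = replace(cfg, seed=sub_seed, **draws)
        skulls.append(generate_skull(sub_cfg, subject=f"S{i + 1:03d}",
                                     rng=sub_rng))
    return skulls
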