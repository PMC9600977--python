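"""Part-counterpart discrepancies, harmony classification and cohort statistics.

Enlow's "millimeter difference method" compares each craniofacial part with
its structural counterpart by simple subtraction; a difference whose
magnitude lies between 0 and 2.5 mm (inclusive) counts as harmonic — the
ideal, balanced configuration. Three horizontal indices are scored:

* skeletal arches:  maxillary − mandibular skeletal arch
* dental arches:    maxillary − mandibular dento-alveolar arch
* MCF − ramus:      middle cranial floor − mandibular ramus
                    (right ramus by convention in the 3D analysis)

The cohort layer compares paired 2D and 3D discrepancy reports: per-index
mean ± SD for each modality, a Kolmogorov–Smirnov normality check per
variable, and a paired Student's t-test per index at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ceph2d import MeasurementSet2D
from .ceph3d import MeasurementSet3D
from .errors import DegenerateTestError
from .errors import EnlowError

__all__ = [
    "HARMONY_THRESHOLD_MM",
    "INDEX_NAMES",
    "DiscrepancyReport",
    "TestResult",
    "CohortTable",
    "discrepancies",
    "classify_harmony",
    "paired_t_test",
    "unpaired_t_test",
    "ks_normality",
    "cohort_summary",
]

#: Default harmonic/non-harmonic boundary (mm), inclusive.
HARMONY_THRESHOLD_MM = 2.5

#: The three part-counterpart indices, in report order.
INDEX_NAMES = ("mcf_ramus", "skeletal_arches", "dental_arches")

INDEX_LABELS = {
    "mcf_ramus": "Middle cranial floor - mandibular ramus",
    "skeletal_arches": "Maxillary - mandibular skeletal arches",
    "dental_arches": "Maxillary - mandibular dento-alveolar arches",
}


@dataclass(frozen=True)
class DiscrepancyReport:
    """Signed part-minus-counterpart values (mm) with harmony labels."""

    subject: str
    dimensionality: str               # "2D" | "3D"
    skeletal_arches: float
    dental_arches: float
    mcf_ramus: float
    harmony: dict[str, str] = field(default_factory=dict)
    threshold: float = HARMONY_THRESHOLD_MM
    ramus_side: str = "right"         # meaningful for 3D only

    def value(self, index: str) -> float:
        return {"mcf_ramus": self.mcf_ramus,
                "skeletal_arches": self.skeletal_arches,
                "dental_arches": self.dental_arches}[index]

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "dimensionality": self.dimensionality,
            "threshold_mm": self.threshold,
            "ramus_side": self.ramus_side,
            "indices": {
                name: {"value_mm": self.value(name),
                       "harmony": self.harmony.get(name)}
                for name in INDEX_NAMES
            },
        }


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single statistical test."""

    statistic: float
    p_value: float
    alpha: float
    degrees_of_freedom: float | None = None
    name: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def classify_harmony(d: float, threshold: float = HARMONY_THRESHOLD_MM) -> str:
    """'harmonic' when |d| ≤ threshold (boundary inclusive), else 'non_harmonic'."""
    if not math.isfinite(d):
        raise EnlowError(f"non-finite discrepancy value: {d}")
    if threshold <= 0:
        raise EnlowError(f"harmony threshold must be positive, got {threshold}")
    return "harmonic" if abs(d) <= threshold else "non_harmonic"


def discrepancies(
    m: MeasurementSet2D | MeasurementSet3D,
    subject: str = "",
    threshold: float = HARMONY_THRESHOLD_MM,
    ramus_side: str = "right",
) -> DiscrepancyReport:
    """Part-minus-counterpart subtraction for one measurement set.

    For 3D measurements ``ramus_side`` selects which ramus feeds the
    MCF − ramus index ('right' by convention; 'left' or 'mean' optional).
    """
    if isinstance(m, MeasurementSet3D):
        dim = "3D"
        ramus = m.ramus(ramus_side)
    elif isinstance(m, MeasurementSet2D):
        dim = "2D"
        ramus = m.ramus
    else:
        raise EnlowError(
            f"expected MeasurementSet2D or MeasurementSet3D, got {type(m).__name__}")

    values = {
        "skeletal_arches": m.maxillary_skeletal - m.mandibular_skeletal,
        "dental_arches": m.maxillary_dental - m.mandibular_dental,
        "mcf_ramus": m.mcf - ramus,
    }
    harmony = {k: classify_harmony(v, threshold) for k, v in values.items()}
    return DiscrepancyReport(
        subject=subject, dimensionality=dim, threshold=threshold,
        ramus_side=ramus_side if dim == "3D" else "n/a",
        harmony=harmony, **values)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _check_sample(x, name: str, n_min: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise EnlowError(f"{name} must be one-dimensional")
    if x.size < n_min:
        raise EnlowError(f"{name} needs at least {n_min} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise EnlowError(f"{name} contains non-finite values")
    return x


def paired_t_test(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided paired Student's t-test on matched samples.

    t = mean(d) / (sd(d)/√n) with d = x − y and the n−1 SD; p from the t
    distribution with n − 1 degrees of freedom. Zero-variance differences
    make the statistic undefined and raise
    :class:`~enlowcp.errors.DegenerateTestError`.
    """
    x = _check_sample(x, "x", 2)
    y = _check_sample(y, "y", 2)
    if x.size != y.size:
        raise EnlowError(f"paired samples differ in length ({x.size} vs {y.size})")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd <= 0.0:
        raise DegenerateTestError(
            "paired differences have zero variance; t statistic undefined")
    n = d.size
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=t, p_value=p, alpha=alpha,
                      degrees_of_freedom=df, name="paired_t")


def unpaired_t_test(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided two-sample Student's t-test (equal variances assumed).

    Offered for sensitivity analysis; the paired test is the default for
    the 2D-vs-3D comparison because both analyses measure the same subject.
    """
    x = _check_sample(x, "x", 2)
    y = _check_sample(y, "y", 2)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    if not np.isfinite(t):
        raise DegenerateTestError("two-sample t statistic undefined (zero variance)")
    return TestResult(statistic=float(t), p_value=float(p), alpha=alpha,
                      degrees_of_freedom=x.size + y.size - 2, name="unpaired_t")


def ks_normality(x, alpha: float = 0.05, lilliefors: bool = False) -> TestResult:
    """Kolmogorov–Smirnov test against a normal fitted by sample mean/SD.

    The classical KS variant: D is the supremum over sample points of the
    gap between the empirical CDF and the fitted normal CDF, and p comes
    from the asymptotic KS distribution. Estimating μ and σ from the same
    sample makes this anti-conservative; pass ``lilliefors=True`` for the
    corrected p-value (off by default to match common clinical usage).
    """
    x = _check_sample(x, "sample", 4)
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0.0:
        raise DegenerateTestError("constant sample; normality test undefined")
    n = x.size
    xs = np.sort(x)
    cdf = stats.norm.cdf(xs, loc=mu, scale=sd)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d_stat = float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        _, p = _lf(x, dist="norm", pvalmethod="table")
        p = float(min(max(p, 0.0), 1.0))
        name = "lilliefors"
    else:
        p = float(stats.kstwobign.sf(math.sqrt(n) * d_stat))
        name = "ks_normality"
    return TestResult(statistic=d_stat, p_value=p, alpha=alpha, name=name)


# ---------------------------------------------------------------------------
# Cohort summary (the 2D-vs-3D comparison table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexSummary:
    """One row of the cohort table (values in the table's unit)."""

    index: str
    mean_2d: float
    sd_2d: float
    mean_3d: float
    sd_3d: float
    normality_2d: TestResult | None
    normality_3d: TestResult | None
    t_test: TestResult | None
    error: str | None = None       # set when a test is degenerate


@dataclass(frozen=True)
class CohortTable:
    """Per-index 2D-vs-3D comparison for a paired cohort."""

    n: int
    unit: str                      # "mm" | "cm"
    alpha: float
    rows: tuple[IndexSummary, ...]

    def row(self, index: str) -> IndexSummary:
        for r in self.rows:
            if r.index == index:
                return r
        raise KeyError(index)

    def to_dataframe(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            recs.append({
                "index": r.index,
                "label": INDEX_LABELS[r.index],
                f"mean_2d_{self.unit}": r.mean_2d,
                f"sd_2d_{self.unit}": r.sd_2d,
                f"mean_3d_{self.unit}": r.mean_3d,
                f"sd_3d_{self.unit}": r.sd_3d,
                "ks_p_2d": r.normality_2d.p_value if r.normality_2d else np.nan,
                "ks_p_3d": r.normality_3d.p_value if r.normality_3d else np.nan,
                "paired_t_p": r.t_test.p_value if r.t_test else np.nan,
                "error": r.error or "",
            })
        return pd.DataFrame.from_records(recs)


def cohort_summary(
    reports_2d: list[DiscrepancyReport],
    reports_3d: list[DiscrepancyReport],
    unit: str = "mm",
    alpha: float = 0.05,
    paired: bool = True,
    lilliefors: bool = False,
) -> CohortTable:
    """Summarise paired 2D and 3D discrepancy reports per index.

    Reports are matched by subject identifier; unpaired subjects raise.
    Means/SDs use the n−1 SD convention; ``unit='cm'`` divides mm values by
    ten for display. Degenerate tests (e.g. identical 2D and 3D values for
    every subject) are surfaced per index in ``error`` rather than aborting
    the whole table.
    """
    if unit not in ("mm", "cm"):
        raise EnlowError(f"unknown unit {unit!r} (expected 'mm' or 'cm')")
    by2 = {r.subject: r for r in reports_2d}
    by3 = {r.subject: r for r in reports_3d}
    if len(by2) != len(reports_2d) or len(by3) != len(reports_3d):
        raise EnlowError("duplicate subject identifiers in cohort reports")
    unpaired = sorted(set(by2) ^ set(by3))
    if unpaired:
        raise EnlowError(f"unpaired subjects in cohort: {', '.join(unpaired)}")
    subjects = sorted(by2)
    n = len(subjects)
    if n < 2:
        raise EnlowError(f"cohort needs at least 2 paired subjects, got {n}")

    scale = 0.1 if unit == "cm" else 1.0
    rows = []
    for index in INDEX_NAMES:
        v2 = np.array([by2[s].value(index) for s in subjects]) * scale
        v3 = np.array([by3[s].value(index) for s in subjects]) * scale
        norm2 = norm3 = ttest = None
        error = None
        try:
            if n >= 4:
                norm2 = ks_normality(v2, alpha=alpha, lilliefors=lilliefors)
                norm3 = ks_normality(v3, alpha=alpha, lilliefors=lilliefors)
            if paired:
                ttest = paired_t_test(v2, v3, alpha=alpha)
            else:
                ttest = unpaired_t_test(v2, v3, alpha=alpha)
        except DegenerateTestError as exc:
            error = str(exc)
        rows.append(IndexSummary(
            index=index,
            mean_2d=float(np.mean(v2)), sd_2d=float(np.std(v2, ddof=1)),
            mean_3d=float(np.mean(v3)), sd_3d=float(np.std(v3, ddof=1)),
            normality_2d=norm2, normality_3d=norm3, t_test=ttest, error=error,
        ))
    return CohortTable(n=n, unit=unit, alpha=alpha, rows=tuple(rows))
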