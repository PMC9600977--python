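"""Discrepancy scoring, harmony classification and cohort statistics."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from enlowcp import (
    classify_harmony,
    cohort_summary,
    discrepancies,
    generate_cohort,
    ks_normality,
    paired_t_test,
    unpaired_t_test,
)
from enlowcp.ceph2d import MeasurementSet2D
from enlowcp.ceph3d import MeasurementSet3D
from enlowcp.counterpart import DiscrepancyReport
from enlowcp.errors import DegenerateTestError, EnlowError
from conftest import F2D_EXPECTED, F3D_EXPECTED


def m2d(**overrides) -> MeasurementSet2D:
    return MeasurementSet2D(**{**F2D_EXPECTED, **overrides})


def m3d(**overrides) -> MeasurementSet3D:
    return MeasurementSet3D(**{**F3D_EXPECTED, **overrides})


class TestDiscrepancies:
    def test_3d_fixture_subtractions(self):
        rep = discrepancies(m3d(), subject="F3D")
        assert rep.skeletal_arches == pytest.approx(-3.0)
        assert rep.dental_arches == pytest.approx(-3.0)
        assert rep.mcf_ramus == pytest.approx(2.0)
        assert rep.dimensionality == "3D"

    def test_2d_fixture_subtractions(self):
        rep = discrepancies(m2d(), subject="F2D")
        assert rep.skeletal_arches == pytest.approx(-8.25)
        assert rep.dental_arches == pytest.approx(-9.25)
        assert rep.mcf_ramus == pytest.approx(11.25)
        assert rep.dimensionality == "2D"

    def test_identical_part_and_counterpart_gives_zero(self):
        rep = discrepancies(m3d(maxillary_skeletal=48.0))
        assert rep.skeletal_arches == 0.0
        assert rep.harmony["skeletal_arches"] == "harmonic"

    def test_ramus_side_convention(self):
        m = m3d(ramus_right=25.0, ramus_left=31.0)
        assert discrepancies(m).mcf_ramus == pytest.approx(27.0 - 25.0)
        assert discrepancies(m, ramus_side="left").mcf_ramus == pytest.approx(
            27.0 - 31.0)
        assert discrepancies(m, ramus_side="mean").mcf_ramus == pytest.approx(
            27.0 - 28.0)

    def test_harmony_labels_follow_threshold(self):
        rep = discrepancies(m3d(), threshold=2.5)
        assert rep.harmony == {"skeletal_arches": "non_harmonic",
                               "dental_arches": "non_harmonic",
                               "mcf_ramus": "harmonic"}


class TestHarmonyClassification:
    @pytest.mark.parametrize("d,label", [
        (0.0, "harmonic"),
        (2.5, "harmonic"),        # boundary inclusive
        (-2.5, "harmonic"),
        (2.5000001, "non_harmonic"),
        (-3.0, "non_harmonic"),
    ])
    def test_boundary(self, d, label):
        assert classify_harmony(d) == label

    def test_sign_symmetry_and_monotonicity(self):
        for d in np.linspace(0, 6, 61):
            assert classify_harmony(d) == classify_harmony(-d)
        labels = [classify_harmony(d) for d in np.linspace(0, 6, 61)]
        # once non-harmonic, always non-harmonic as |d| grows
        first_bad = labels.index("non_harmonic")
        assert all(l == "non_harmonic" for l in labels[first_bad:])

    def test_non_finite_rejected(self):
        with pytest.raises(EnlowError):
            classify_harmony(float("nan"))

    def test_custom_threshold(self):
        assert classify_harmony(3.0, threshold=3.5) == "harmonic"
        with pytest.raises(EnlowError):
            classify_harmony(1.0, threshold=0.0)


class TestPairedT:
    def test_closed_form_example(self):
        """Differences {1,2,3}: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641."""
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-9)
        assert res.degrees_of_freedom == 2
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)
        assert not res.reject

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = paired_t_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 5.0, 4.0], [0.5, 2.5, 3.0, 1.0]
        a, b = paired_t_test(x, y), paired_t_test(y, x)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p_value == pytest.approx(a.p_value)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateTestError):
            paired_t_test([1.0, 2.0], [0.0, 1.0])  # constant difference

    def test_length_mismatch_rejected(self):
        with pytest.raises(EnlowError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_critical_value_df2(self):
        """Root-finding on the implemented p-value recovers the published
        two-sided critical value 4.3027 at alpha = 0.05, df = 2."""
        crit = brentq(lambda t: 2 * stats.t.sf(t, 2) - 0.05, 1.0, 20.0)
        assert crit == pytest.approx(4.3027, abs=1e-3)
        # and the implementation uses that same distribution
        res = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p_value == pytest.approx(2 * stats.t.sf(res.statistic, 2),
                                            abs=1e-12)

    def test_unpaired_option(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(0.3, 1.0, size=15)
        res = unpaired_t_test(x, y)
        ref = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.degrees_of_freedom == 25


def brute_force_ks_statistic(x: np.ndarray) -> float:
    """Oracle: maximize both one-sided ECDF-vs-fitted-normal gaps at every
    sample point by direct enumeration."""
    n = len(x)
    mu, sd = np.mean(x), np.std(x, ddof=1)
    best = 0.0
    xs = np.sort(x)
    for i, xi in enumerate(xs):
        f = stats.norm.cdf(xi, mu, sd)
        best = max(best, abs((i + 1) / n - f), abs(i / n - f))
    return best


class TestKSNormality:
    def test_statistic_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n)
            res = ks_normality(x)
            assert res.statistic == pytest.approx(brute_force_ks_statistic(x),
                                                  abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        a = ks_normality(x)
        b = ks_normality(3.7 * x - 11.0)
        assert b.statistic == pytest.approx(a.statistic, abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_heavy_tailed_sample_rejected(self):
        rng = np.random.default_rng(123)
        x = rng.standard_cauchy(size=500)
        res = ks_normality(x)
        assert res.reject

    def test_gaussian_sample_not_rejected(self):
        rng = np.random.default_rng(8)
        res = ks_normality(rng.normal(size=500))
        assert not res.reject

    def test_small_sample_rejected(self):
        with pytest.raises(EnlowError):
            ks_normality([1.0, 2.0, 3.0])

    def test_lilliefors_correction_is_more_conservative(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        classical = ks_normality(x)
        corrected = ks_normality(x, lilliefors=True)
        assert corrected.statistic == pytest.approx(classical.statistic,
                                                    abs=1e-12)
        assert corrected.p_value <= classical.p_value + 1e-9


def _reports(values, dim, prefix="S"):
    out = []
    for i, (sk, de, mr) in enumerate(values):
        out.append(DiscrepancyReport(
            subject=f"{prefix}{i}", dimensionality=dim,
            skeletal_arches=sk, dental_arches=de, mcf_ramus=mr))
    return out


class TestCohortSummary:
    def test_means_and_sds_match_brute_force(self):
        rng = np.random.default_rng(10)
        vals2 = rng.normal(0, 2, size=(10, 3))
        vals3 = rng.normal(0.2, 2, size=(10, 3))
        table = cohort_summary(_reports(vals2, "2D"), _reports(vals3, "3D"))
        assert table.n == 10
        for j, index in enumerate(("skeletal_arches", "dental_arches",
                                   "mcf_ramus")):
            row = table.row(index)
            assert row.mean_2d == pytest.approx(vals2[:, j].mean())
            assert row.sd_2d == pytest.approx(vals2[:, j].std(ddof=1))
            assert row.mean_3d == pytest.approx(vals3[:, j].mean())
            assert row.sd_3d == pytest.approx(vals3[:, j].std(ddof=1))
            ref = stats.ttest_rel(vals2[:, j], vals3[:, j])
            assert row.t_test.p_value == pytest.approx(ref.pvalue)

    def test_cm_units_divide_by_ten(self):
        rng = np.random.default_rng(11)
        vals2 = rng.normal(0, 2, size=(6, 3))
        vals3 = rng.normal(0, 2, size=(6, 3))
        mm = cohort_summary(_reports(vals2, "2D"), _reports(vals3, "3D"),
                            unit="mm")
        cm = cohort_summary(_reports(vals2, "2D"), _reports(vals3, "3D"),
                            unit="cm")
        for index in ("skeletal_arches", "dental_arches", "mcf_ramus"):
            assert cm.row(index).mean_2d == pytest.approx(
                mm.row(index).mean_2d / 10.0)
            assert cm.row(index).sd_3d == pytest.approx(
                mm.row(index).sd_3d / 10.0)
            # the paired t-test is scale invariant
            assert cm.row(index).t_test.p_value == pytest.approx(
                mm.row(index).t_test.p_value)

    def test_identical_reports_surface_degenerate_tests(self):
        vals = [(1.0, -2.0, 0.5), (1.5, -1.0, 0.2), (0.5, -3.0, 0.9),
                (2.0, -2.5, 0.1)]
        table = cohort_summary(_reports(vals, "2D"), _reports(vals, "3D"))
        for row in table.rows:
            assert row.error is not None and "zero variance" in row.error
            assert row.t_test is None
            assert row.mean_2d == pytest.approx(row.mean_3d)

    def test_unpaired_subjects_listed(self):
        r2 = _reports([(1, 2, 3), (4, 5, 6)], "2D", prefix="A")
        r3 = _reports([(1, 2, 3), (4, 5, 6)], "3D", prefix="B")
        with pytest.raises(EnlowError, match="A0"):
            cohort_summary(r2, r3)

    def test_no_planted_shift_stays_within_three_standard_errors(self):
        """A synthetic cohort with identical 2D/3D templates shows
        |mean2D − mean3D| below 3 standard errors for every index."""
        from enlowcp import analyze_2d, analyze_3d

        skulls = generate_cohort(18, seed=42)
        r2 = [discrepancies(analyze_2d(s.lm2d)[1], subject=s.subject)
              for s in skulls]
        r3 = [discrepancies(analyze_3d(s.lm3d)[1], subject=s.subject)
              for s in skulls]
        table = cohort_summary(r2, r3)
        for row in table.rows:
            diff = abs(row.mean_2d - row.mean_3d)
            se = np.hypot(row.sd_2d, row.sd_3d) / np.sqrt(table.n)
            assert diff < 3.0 * se + 1e-9
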