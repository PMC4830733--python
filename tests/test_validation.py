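"""Calibration, detection limits, recovery, and precision ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressdoe import (
    DataError,
    PrecisionLevel,
    assay_content,
    coefficient_t_tests,
    detection_limits,
    fit_calibration,
    precision_anova,
    recovery_regression,
)
from stressdoe import datasets


def exact_line(slope=100000.0, intercept=500.0, reps=1):
    rows = []
    for c in (2, 4, 6, 8, 10, 12):
        for r in range(reps):
            rows.append((float(c), slope * c + intercept))
    return rows


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration(exact_line())
        assert curve.slope == pytest.approx(100000.0)
        assert curve.intercept == pytest.approx(500.0)
        assert curve.correlation == pytest.approx(1.0)
        assert curve.exact_fit
        assert curve.linearity_f == np.inf

    def test_linearity_f_critical_for_six_levels(self):
        """Mean aggregation of six levels tests linearity on (1, 4) df."""
        rng = np.random.default_rng(7)
        pts = [(c, 100000 * c + 500 + rng.normal(0, 800)) for c, _ in exact_line()]
        curve = fit_calibration(pts)
        assert curve.df_resid == 4
        assert curve.f_critical_linearity == pytest.approx(7.71, abs=0.01)
        assert curve.linearity_f > curve.f_critical_linearity

    def test_closed_form_slope_intercept(self):
        """Slope/intercept equal the covariance/variance expressions."""
        rng = np.random.default_rng(11)
        pts = [(c, 90000 * c + 300 + rng.normal(0, 500)) for c, _ in exact_line()]
        curve = fit_calibration(pts, aggregate="raw")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_slope_estimate_unbiased(self):
        """Noisy refits recover the true slope within Monte-Carlo error."""
        rng = np.random.default_rng(2026)
        true_slope, noise_sd = 100000.0, 0.01 * 100000.0 * 7.0  # 1% of mid-range
        n_sims = 500
        slopes = np.empty(n_sims)
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        for i in range(n_sims):
            y = 500.0 + true_slope * x + rng.normal(0, noise_sd, size=6)
            slopes[i] = fit_calibration(list(zip(x, y))).slope
        se_slope = noise_sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slopes.mean() - true_slope) < 4 * se_slope / np.sqrt(n_sims)

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(DataError):
            fit_calibration([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])


class TestCoefficientTTests:
    def test_exact_fit_flagged(self):
        curve = fit_calibration(exact_line())
        res = coefficient_t_tests(curve, slope_null=100000.0, intercept_null=500.0)
        assert res.exact_fit
        assert res.slope_t == 0.0
        assert res.intercept_t == 0.0

    def test_zero_slope_null_is_strongly_rejected(self):
        rng = np.random.default_rng(3)
        pts = [(c, 100000 * c + 500 + rng.normal(0, 300)) for c, _ in exact_line()]
        res = coefficient_t_tests(fit_calibration(pts), slope_null=0.0)
        assert abs(res.slope_t) > 100
        assert res.slope_p < 1e-3

    def test_true_null_type_one_error(self):
        """|t| < t_crit in about 95% of simulations under the null."""
        rng = np.random.default_rng(99)
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        tcrit = stats.t.ppf(0.975, 4)
        n_sims, accept = 500, 0
        for _ in range(n_sims):
            y = 100.0 * x + 0.0 + rng.normal(0, 25.0, size=6)  # true intercept 0
            res = coefficient_t_tests(fit_calibration(list(zip(x, y))), 100.0, 0.0)
            if abs(res.intercept_t) < tcrit:
                accept += 1
        assert 0.90 <= accept / n_sims <= 0.99


class TestDetectionLimits:
    def test_formula(self):
        dl = detection_limits(1.0, 10.0)
        assert dl.dl == pytest.approx(0.33)
        assert dl.ql == pytest.approx(1.0)

    def test_zero_sd(self):
        dl = detection_limits(0.0, 10.0)
        assert dl.dl == 0.0 and dl.ql == 0.0

    def test_published_slope_back_solved_sd(self):
        """A response SD of ~24200 area units reproduces a 0.678 ug/mL DL."""
        dl = detection_limits(24200.0, 117762.0)
        assert dl.dl == pytest.approx(0.678, abs=0.001)

    @pytest.mark.parametrize("sd,slope", [(1.0, 10.0), (24200.0, 117762.0), (3.7, 0.5)])
    def test_ql_dl_ratio_fixed(self, sd, slope):
        dl = detection_limits(sd, slope)
        assert dl.ql == pytest.approx(dl.dl * 10.0 / 3.3)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(DataError):
            detection_limits(1.0, 0.0)


class TestPrecisionAnova:
    @pytest.mark.parametrize(
        "label, bms, wms, f",
        [
            ("80% (10 mg)", 0.00028, 0.0009, 0.3086),
            ("100% (12.5 mg)", 0.00174, 0.00208, 0.8396),
            ("120% (15 mg)", 0.0012, 0.00078, 1.508),
        ],
    )
    def test_study_levels(self, label, bms, wms, f):
        level = next(l for l in datasets.precision_levels() if l.level_label == label)
        an = level.anova()
        for got, want in ((an.bms, bms), (an.wms, wms), (an.f_value, f)):
            decimals = len(str(want).split(".")[1])
            assert round(got, decimals) == want
        assert an.df_between == 2 and an.df_within == 6
        assert an.f_value < stats.f.ppf(0.95, 2, 6)  # ~5.14: good precision

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_f_oneway(self, seed):
        rng = np.random.default_rng(seed)
        d, r = rng.integers(2, 5), rng.integers(2, 6)
        values = rng.normal(10, 1, size=(d, r))
        an = precision_anova(values)
        ref = stats.f_oneway(*values)
        assert an.f_value == pytest.approx(ref.statistic, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_sum_of_squares_identity(self, seed):
        """BMS*df_b + WMS*df_w equals the total corrected SS."""
        rng = np.random.default_rng(100 + seed)
        values = rng.normal(0, 2, size=(3, 3))
        an = precision_anova(values)
        total = float(np.sum((values - values.mean()) ** 2))
        assert an.bms * an.df_between + an.wms * an.df_within == pytest.approx(
            total, rel=1e-12, abs=1e-12
        )

    def test_identical_values_degenerate(self):
        an = precision_anova(np.full((3, 3), 12.5))
        assert an.degenerate
        assert np.isnan(an.f_value)

    def test_unbalanced_rejected(self):
        with pytest.raises(DataError):
            precision_anova([[1.0, 2.0], [1.0, 2.0, 3.0]])

    def test_too_small_rejected(self):
        with pytest.raises(DataError):
            precision_anova(np.ones((1, 3)))


class TestRecovery:
    def test_perfect_recovery(self):
        pairs = [(a, a) for a in (10.0, 12.5, 15.0) for _ in range(3)]
        res = recovery_regression(pairs)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(100.0) for v in res.recovery_pct.values())

    def test_study_level_means(self):
        """Least squares on the three study level means gives slope ~0.803."""
        res = recovery_regression(datasets.recovery_pairs(), on="means")
        assert res.slope == pytest.approx(0.803, abs=0.002)
        assert res.recovery_pct[10.0] == pytest.approx(100.3, abs=0.1)
        assert res.recovery_pct[15.0] == pytest.approx(93.7, abs=0.1)

    def test_scale_equivariance(self):
        pairs = [(10.0, 10.2), (12.5, 12.4), (15.0, 14.8)]
        scaled = [(a * 3.0, f * 3.0) for a, f in pairs]
        assert recovery_regression(scaled).slope == pytest.approx(
            recovery_regression(pairs).slope
        )

    def test_single_level_rejected(self):
        with pytest.raises(DataError):
            recovery_regression([(10.0, 10.1), (10.0, 9.9)])


class TestAssayContent:
    def test_on_curve_is_100pct(self):
        curve = fit_calibration(exact_line())
        area = curve.predict(10.0)
        assert assay_content(area, curve, 10.0) == pytest.approx(100.0)

    def test_zero_intercept_scaling(self):
        curve = fit_calibration([(c, 1000.0 * c) for c in (2, 4, 6, 8, 10, 12)])
        assert assay_content(1000.0 * 11.0, curve, 10.0) == pytest.approx(110.0)

    def test_triplicate_inverse_of_generation(self):
        """Areas generated at 101.28% of nominal assay back to 101.28%."""
        curve = fit_calibration(exact_line())
        nominal = 10.0
        areas = curve.predict(np.full(3, nominal * 1.0128))
        out = assay_content(areas, curve, nominal)
        assert np.mean(out) == pytest.approx(101.28)
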