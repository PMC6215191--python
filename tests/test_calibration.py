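"""Calibration fitting, inversion, Huber plot and lack-of-fit ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cyanoval as cv
from cyanoval.calibration import CalibrationCurve
from cyanoval.simulate import noiseless

from conftest import ols_oracle


def _records(x, y, analyte="X"):
    return pd.DataFrame(
        {"analyte_id": analyte, "nominal_conc": np.asarray(x, float),
         "response": np.asarray(y, float)}
    )


class TestFitCalibration:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        curve = cv.fit_calibration(_records(x, [3.0, 5.0, 7.0, 9.0]))
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(1.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_reference_coefficients_from_noiseless_data(self, mclr, design):
        records = cv.simulate_calibration(noiseless(mclr), design, matrix=False, seed=0)
        curve = cv.fit_calibration(records)
        assert curve.slope == pytest.approx(127.47, rel=1e-9)
        assert curve.intercept == pytest.approx(1.0247, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = np.sort(rng.uniform(0.2, 75, size=12))
            y = 1.0 + 100 * x + rng.normal(0, 5, size=12)
            curve = cv.fit_calibration(_records(x, y))
            a, b = ols_oracle(x, y)
            assert curve.slope == pytest.approx(b, rel=1e-10)
            assert curve.intercept == pytest.approx(a, rel=1e-10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(cv.FitError):
            cv.fit_calibration(_records([1, 1, 2, 2], [1, 1, 2, 2]))

    @given(
        c=st.floats(min_value=0.1, max_value=100),
        d=st.floats(min_value=-50, max_value=50),
    )
    def test_r_squared_invariant_to_affine_response_rescaling(self, c, d):
        rng = np.random.default_rng(1)
        x = np.arange(1.0, 9.0)
        y = 2 + 3 * x + rng.normal(0, 0.5, x.size)
        r2 = cv.fit_calibration(_records(x, y)).r_squared
        r2_scaled = cv.fit_calibration(_records(x, c * y + d)).r_squared
        assert r2_scaled == pytest.approx(r2, rel=1e-8)


class TestInvertCalibration:
    curve = CalibrationCurve("MC-LR", 127.47, 1.0247, 1.0, 12, 0.0)

    def test_intercept_maps_to_zero(self):
        assert cv.invert_calibration(self.curve, 1.0247) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_at_20(self):
        assert cv.invert_calibration(
            self.curve, 1.0247 + 127.47 * 20
        ) == pytest.approx(20.0, rel=1e-12)

    def test_below_intercept_negative_unclamped(self):
        assert cv.invert_calibration(self.curve, 0.0) < 0

    def test_zero_slope_rejected(self):
        flat = CalibrationCurve("X", 0.0, 1.0, 1.0, 3, 0.0)
        with pytest.raises(cv.InversionError):
            cv.invert_calibration(flat, 5.0)

    def test_fit_invert_identity_on_noiseless_data(self, mclr, design):
        records = cv.simulate_calibration(noiseless(mclr), design, matrix=True, seed=0)
        curve = cv.fit_calibration(records)
        conc = curve.inverse(records["response"].to_numpy())
        np.testing.assert_allclose(conc, records["nominal_conc"], rtol=1e-9, atol=1e-9)


class TestHuberLinearity:
    def test_proportional_data_passes(self):
        x = np.array([0.5, 1.0, 5.0, 20.0, 75.0])
        res = cv.huber_linearity(_records(x, 100.0 * x))
        assert res.passed
        assert set(res.factors_by_level.values()) == {100.0}

    def test_factors_within_band(self):
        x = np.repeat([1.0, 2.0, 3.0], 1)
        y = np.array([100.0, 2 * 104.0, 3 * 96.1])
        res = cv.huber_linearity(_records(x, y))
        assert res.target == pytest.approx(100.0)
        assert res.passed

    def test_excursion_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([106.0, 2 * 100.0, 3 * 100.0])
        res = cv.huber_linearity(_records(x, y))
        assert not res.pass_by_level[1.0]
        assert not res.passed

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = np.repeat([1.0, 5.0, 20.0, 75.0], 3)
        y = 50 * x * (1 + rng.normal(0, 0.02, x.size))
        res = cv.huber_linearity(_records(x, y))
        res_scaled = cv.huber_linearity(_records(x, 7.5 * y))
        assert res.pass_by_level == res_scaled.pass_by_level

    def test_zero_level_rejected(self):
        with pytest.raises(cv.DesignError):
            cv.huber_linearity(_records([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))


def lof_oracle(x, y):
    """Two-step brute-force lack-of-fit ANOVA, independent of the library."""
    a, b = ols_oracle(x, y)
    fitted = a + b * x
    levels = np.unique(x)
    ss_pe = 0.0
    ss_lof = 0.0
    for lv in levels:
        sel = x == lv
        m = y[sel].mean()
        ss_pe += ((y[sel] - m) ** 2).sum()
        ss_lof += sel.sum() * (m - (a + b * lv)) ** 2
    df_lof = levels.size - 2
    df_pe = x.size - levels.size
    return ss_lof, ss_pe, (ss_lof / df_lof) / (ss_pe / df_pe)


class TestLackOfFit:
    def test_level_means_on_line_give_zero_f(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 2)
        y = 2.0 * x + np.tile([-0.5, 0.5], 4)  # symmetric replicate noise
        res = cv.lack_of_fit_anova(_records(x, y))
        assert res.ms_lack_of_fit == pytest.approx(0.0, abs=1e-18)
        assert res.f_ratio == pytest.approx(0.0, abs=1e-12)
        assert res.passed

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = np.repeat([1.0, 2.0, 3.0, 4.0], 2)
            y = 1.0 + 2.0 * x + rng.normal(0, 0.3, x.size)
            res = cv.lack_of_fit_anova(_records(x, y))
            ss_lof, ss_pe, f = lof_oracle(x, y)
            assert res.f_ratio == pytest.approx(f, rel=1e-10)
            assert res.ms_lack_of_fit * res.df_lof == pytest.approx(ss_lof, rel=1e-10)
            assert res.ms_pure_error * res.df_pe == pytest.approx(ss_pe, rel=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_sum_of_squares_conservation(self, seed):
        rng = np.random.default_rng(seed)
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 2)
        y = rng.normal(0, 1, x.size) + x
        records = _records(x, y)
        res = cv.lack_of_fit_anova(records)
        curve = cv.fit_calibration(records)
        ss_res = float(np.sum((y - curve.predict(x)) ** 2))
        total = res.ms_lack_of_fit * res.df_lof + res.ms_pure_error * res.df_pe
        assert total == pytest.approx(ss_res, rel=1e-8, abs=1e-12)

    def test_f_critical_follows_supplied_df(self):
        # 12 levels x 3 replicates -> (10, 24) df
        rng = np.random.default_rng(4)
        x = np.repeat(np.arange(1.0, 13.0), 3)
        y = x * 5 + rng.normal(0, 0.1, x.size)
        res = cv.lack_of_fit_anova(_records(x, y))
        assert (res.df_lof, res.df_pe) == (10, 24)
        assert res.f_critical == pytest.approx(stats.f.ppf(0.95, 10, 24), rel=1e-12)

    def test_tabulated_bound_at_10_2_df(self):
        assert round(float(stats.f.ppf(0.95, 10, 2)), 1) == 19.4

    def test_no_replication_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(cv.DesignError):
            cv.lack_of_fit_anova(_records(x, 2 * x))
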