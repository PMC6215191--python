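"""Generator contracts: exact noiseless values, moments, layout, round-trips."""

import numpy as np
import pandas as pd
import pytest

import cyanoval as cv
from cyanoval.simulate import AnalyteModel, StudyDesign, noiseless


def _model(**kw):
    base = dict(
        analyte_id="X",
        slope=2.0,
        intercept=1.0,
        recovery_fraction_by_level={20.0: 0.93},
        within_day_sd_by_level={20.0: 0.0},
        day_effect_sd_by_level={20.0: 0.0},
    )
    base.update(kw)
    return AnalyteModel(**base)


class TestAnalyteModel:
    def test_nonpositive_slope_rejected(self):
        with pytest.raises(cv.ModelError):
            _model(slope=0.0)
        with pytest.raises(cv.ModelError):
            _model(slope=-1.0)

    def test_negative_sds_rejected(self):
        with pytest.raises(cv.ModelError):
            _model(within_day_sd_by_level={20.0: -0.1})
        with pytest.raises(cv.ModelError):
            _model(blank_sd=-1.0)

    def test_recovery_fraction_bounds(self):
        with pytest.raises(cv.ModelError):
            _model(recovery_fraction_by_level={20.0: 0.0})
        with pytest.raises(cv.ModelError):
            _model(recovery_fraction_by_level={20.0: 1.6})

    def test_nearest_level_lookup(self):
        m = _model(within_day_sd_by_level={5.0: 0.2, 50.0: 4.6})
        assert m.within_day_sd(5.0) == 0.2
        assert m.within_day_sd(6.0) == 0.2
        assert m.within_day_sd(40.0) == 4.6


class TestSimulateCalibration:
    def test_noiseless_responses_on_reference_line(self, mclr, design):
        records = cv.simulate_calibration(noiseless(mclr), design, matrix=False, seed=0)
        expected = 1.0247 + 127.47 * records["nominal_conc"]
        np.testing.assert_allclose(records["response"], expected, rtol=1e-12)
        assert len(records) == 12 * 3

    def test_noiseless_level_zero_gives_intercept(self):
        m = _model()
        d = StudyDesign(calibration_levels=(0.0, 10.0, 20.0))
        records = cv.simulate_calibration(m, d, matrix=False, seed=0)
        at_zero = records[records["nominal_conc"] == 0.0]["response"]
        assert (at_zero == 1.0).all()

    def test_matrix_flag_scales_slope(self):
        m = _model(matrix_slope_ratio=1.25)
        d = StudyDesign(calibration_levels=(1.0, 2.0, 4.0))
        solvent = cv.simulate_calibration(m, d, matrix=False, seed=0)
        matrix = cv.simulate_calibration(m, d, matrix=True, seed=0)
        np.testing.assert_allclose(
            matrix["response"] - 1.0, (solvent["response"] - 1.0) * 1.25, rtol=1e-12
        )

    def test_back_computed_sd_matches_generating_sd(self):
        m = _model(within_day_sd_by_level={20.0: 1.5})
        d = StudyDesign(
            calibration_levels=(5.0, 20.0, 50.0), calibration_replicates=10_000
        )
        records = cv.simulate_calibration(m, d, matrix=False, seed=42)
        at20 = records[records["nominal_conc"] == 20.0]
        conc = (at20["response"] - 1.0) / 2.0
        assert np.std(conc, ddof=1) == pytest.approx(1.5, rel=0.03)

    def test_fixed_seed_reproducible(self, mclr, design):
        a = cv.simulate_calibration(mclr, design, seed=3)
        b = cv.simulate_calibration(mclr, design, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateBlanks:
    def test_zero_sd_all_equal_mean(self):
        m = _model(blank_mean=3.0, blank_sd=0.0)
        records = cv.simulate_blanks(m, n=10, seed=0)
        assert (records["response"] == 3.0).all()

    def test_cardinality_and_type(self):
        records = cv.simulate_blanks(_model(blank_mean=3.0, blank_sd=1.0), n=10, seed=0)
        assert len(records) == 10
        assert (records["sample_type"] == "blank").all()
        assert (records["nominal_conc"] == 0.0).all()

    def test_moments_at_large_n(self):
        m = _model(blank_mean=3.21, blank_sd=1.821)
        records = cv.simulate_blanks(m, n=100_000, seed=11)
        y = records["response"]
        assert y.mean() == pytest.approx(3.21, rel=0.01)
        assert y.std(ddof=1) == pytest.approx(1.821, rel=0.01)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(cv.DesignError):
            cv.simulate_blanks(_model(), n=1, seed=0)


class TestSimulatePrecisionStudy:
    def test_noiseless_back_computed_concentration(self):
        m = _model()  # recovery 0.93, all SDs zero
        d = StudyDesign(validation_levels=(20.0,))
        records = cv.simulate_precision_study(m, d, seed=0)
        conc = (records["response"] - 1.0) / 2.0
        np.testing.assert_allclose(conc, 18.6, rtol=1e-12)

    def test_default_layout_27_records(self, mclr, design):
        records = cv.simulate_precision_study(mclr, design, seed=0)
        assert len(records) == 3 * 3 * 3
        counts = records.groupby(["nominal_conc", "day"]).size()
        assert (counts == 3).all()

    def test_day_effect_shared_within_day(self):
        m = _model(
            within_day_sd_by_level={20.0: 0.0}, day_effect_sd_by_level={20.0: 1.0}
        )
        d = StudyDesign(validation_levels=(20.0,))
        records = cv.simulate_precision_study(m, d, seed=5)
        per_day_sd = records.groupby("day")["response"].std()
        assert (per_day_sd == 0).all()
        assert records.groupby("day")["response"].mean().nunique() == 3

    def test_variance_component_recovery(self):
        # average the ANOVA day-component estimate over 8 long studies
        m = _model(
            within_day_sd_by_level={20.0: 1.38}, day_effect_sd_by_level={20.0: 0.8}
        )
        d = StudyDesign(validation_levels=(20.0,), days=200)
        ests_day, ests_within = [], []
        for seed in range(8):
            records = cv.simulate_precision_study(m, d, seed=seed)
            conc = (records["response"] - 1.0) / 2.0
            frame = pd.DataFrame({"day": records["day"], "concentration": conc})
            a = cv.anova_by_day(frame)
            _, _, s_day, _ = cv.precision_components(a.ms_within, a.ms_between, 3)
            ests_day.append(s_day)
            ests_within.append(np.sqrt(a.ms_within))
        assert np.mean(ests_day) == pytest.approx(0.8, rel=0.05)
        assert np.mean(ests_within) == pytest.approx(1.38, rel=0.05)


class TestSimulateYoudenRuns:
    def test_zero_shift_zero_noise_identical(self, design):
        records = cv.simulate_youden_runs(_model(), design, seed=0)
        assert records["response"].nunique() == 1
        assert len(records) == 8

    def test_combo_labels_complete(self, design):
        records = cv.simulate_youden_runs(_model(), design, seed=0)
        assert sorted(records["youden_combo"]) == [f"C{i}" for i in range(1, 9)]

    def test_injected_shift_recovered_as_effect(self, design):
        records = cv.simulate_youden_runs(
            _model(), design, factor_shifts={"F1": 2.0}, seed=0
        )
        conc = (records["response"] - 1.0) / 2.0
        results = pd.DataFrame({"combo": records["youden_combo"], "concentration": conc})
        effects = cv.factor_effects(results)
        assert effects["F1"] == pytest.approx(2.0, abs=1e-12)
        assert effects["F2"] == pytest.approx(0.0, abs=1e-12)
        assert effects["F3"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_factor_rejected(self, design):
        with pytest.raises(cv.ConfigError):
            cv.simulate_youden_runs(_model(), design, factor_shifts={"F9": 1.0}, seed=0)


class TestBundle:
    def test_fixed_seed_byte_identical(self, models, design):
        a = cv.simulate.simulate_bundle(models, design, seed=1).to_csv(index=False)
        b = cv.simulate.simulate_bundle(models, design, seed=1).to_csv(index=False)
        assert a == b

    def test_contains_all_stages(self, bundle):
        types = set(bundle["sample_type"])
        assert types == {"solvent_std", "matrix_std", "blank", "spike", "youden"}
        assert set(bundle["analyte_id"]) == set(cv.simulate.ANALYTES)

    def test_transitions_metadata(self):
        t = cv.simulate.transitions_table()
        quant = t[t["role"] == "quantifier"]
        assert quant.groupby("analyte_id").size().eq(1).all()


class TestMeasurementIO:
    def test_round_trip_lossless(self, mclr, design, tmp_path):
        records = cv.simulate_precision_study(mclr, design, seed=9)
        path = tmp_path / "m.csv"
        cv.write_measurements(records, path)
        back = cv.read_measurements(path)
        pd.testing.assert_frame_equal(records, back)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(cv.ParseError):
            cv.read_measurements(path)

    def test_non_numeric_response_names_line(self, mclr, design, tmp_path):
        records = cv.simulate_blanks(mclr, n=4, seed=0)
        path = tmp_path / "m.csv"
        cv.write_measurements(records, path)
        lines = path.read_text().splitlines()
        lines[3] = lines[3].rsplit(",", 2)[0] + ",oops,"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(cv.ParseError) as err:
            cv.read_measurements(path)
        assert err.value.line == 4
        assert "oops" in str(err.value)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(cv.ParseError):
            cv.read_measurements(path)
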