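import numpy as np
import pandas as pd
import pytest

import lfaquant as lq
from lfaquant import calibration as cal


def simulate_line(seed, n_conc=8, reps=3, sigma=0.05, slope=1.0, intercept=0.0):
    rng = np.random.default_rng(seed)
    x = np.repeat(np.arange(n_conc, dtype=float), reps)
    y = intercept + slope * x + rng.normal(0, sigma, x.size)
    return cal.CalibrationData(x, y)


@pytest.fixture
def exact_line():
    x = np.repeat([0.0, 1.0, 2.0, 3.0], 2)
    return cal.CalibrationData(x, 1.0 + 2.0 * x)


class TestResponseDefinition:
    @pytest.mark.parametrize("expr,tl,cl,expected", [
        ("tl/cl", 0.4, 0.2, 2.0),
        ("cl/tl", 0.2, 0.4, 2.0),
        ("tl", 0.4, 0.2, 0.4),
        ("tl/(tl+cl)", 0.4, 0.2, 0.4 / 0.6),
    ])
    def test_known_ratios(self, expr, tl, cl, expected):
        table = pd.DataFrame({"tl_mean": [tl], "cl_mean": [cl]})
        y, ok = cal.ResponseDefinition(expr).evaluate(table)
        assert ok[0]
        assert y[0] == pytest.approx(expected)

    def test_zero_denominator_dropped_and_logged(self, caplog):
        table = pd.DataFrame({"tl_mean": [0.0, 0.5], "cl_mean": [0.2, 0.1],
                              "concentration": [1.0, 2.0]})
        with caplog.at_level("WARNING", logger="lfaquant"):
            data = cal.make_response(table, cal.ResponseDefinition("cl/tl"),
                                     "concentration")
        assert data.n == 1
        assert "dropped 1" in caplog.text

    def test_median_statistic_selects_median_columns(self):
        table = pd.DataFrame({"tl_median": [0.3], "cl_median": [0.1]})
        y, _ = cal.ResponseDefinition("tl/cl", statistic="median").evaluate(table)
        assert y[0] == pytest.approx(3.0)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(cal.SchemaError):
            cal.ResponseDefinition("tl/cl").evaluate(pd.DataFrame({"tl_mean": [1.0]}))

    def test_arbitrary_expression_rejected(self):
        with pytest.raises(ValueError):
            cal.ResponseDefinition("tl + cl")


class TestLinearFit:
    def test_exact_line_recovers_coefficients_and_r2(self, exact_line):
        model, metrics = cal.fit_calibration(exact_line, "linear")
        b0, b1 = model.params["beta"]
        assert b0 == pytest.approx(1.0, abs=1e-10)
        assert b1 == pytest.approx(2.0, abs=1e-10)
        assert metrics.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_within_three_standard_errors(self):
        data = simulate_line(seed=42, slope=2.0, intercept=1.0)
        model, _ = cal.fit_calibration(data, "linear")
        b0, b1 = model.params["beta"]
        se0, se1 = model.params["bse"]
        assert abs(b0 - 1.0) < 3 * se0
        assert abs(b1 - 2.0) < 3 * se1

    def test_r2_equals_squared_pearson_correlation(self, rng):
        data = simulate_line(seed=7, sigma=0.3)
        model, metrics = cal.fit_calibration(data, "linear")
        yhat = model.predict(data.x)
        r = np.corrcoef(data.y, yhat)[0, 1]
        assert metrics.r2 == pytest.approx(r ** 2)

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(cal.DataError):
            cal.fit_calibration(
                cal.CalibrationData([1.0, 1.0], [0.1, 0.2]), "linear")


class TestSmoothers:
    def test_local_poly_reproduces_smooth_curve(self):
        x = np.linspace(0, 10, 40)
        y = 0.1 + 0.05 * x ** 2
        data = cal.CalibrationData(x, y)
        model, metrics = cal.fit_calibration(data, "local_poly")
        assert metrics.r2 is None  # R^2 restricted to the linear model
        pred = model.predict(x)
        assert np.abs(pred - y).max() < 1e-6  # quadratic is exact for degree 2

    def test_spline_additive_noise_free_quadratic(self):
        x = np.repeat(np.linspace(0, 10, 9), 3)
        y = 0.2 + 0.03 * x ** 2
        model, _ = cal.fit_calibration(cal.CalibrationData(x, y),
                                       "spline_additive")
        pred = model.predict(x)
        assert np.abs(pred - y).max() < 1e-3

    def test_smoothers_require_five_distinct_x(self):
        data = cal.CalibrationData([0, 1, 2, 3.0], [0, 1, 2, 3.0])
        for kind in ("local_poly", "spline_additive"):
            with pytest.raises(cal.DataError):
                cal.fit_calibration(data, kind)

    def test_monotone_flag_set_on_monotone_fit(self):
        x = np.repeat(np.linspace(0, 10, 8), 2)
        y = np.log1p(x) + 0.2
        model, _ = cal.fit_calibration(cal.CalibrationData(x, y),
                                       "spline_additive")
        assert model.monotone_direction == 1
        grid = np.linspace(0, 10, 100)
        assert (np.diff(model.predict(grid)) > 0).all()


class TestDetectionLimits:
    def test_closed_form_on_unit_slope(self):
        # y = x, blanks with sd 0.02 around 0
        rng = np.random.default_rng(0)
        blanks = np.array([-0.02, 0.02, 0.0, 0.0])  # mean 0, sd known
        x = np.r_[np.zeros(4), np.repeat([1.0, 2, 4, 8], 2)]
        y = np.r_[blanks, np.repeat([1.0, 2, 4, 8], 2)]
        data = cal.CalibrationData(x, y)
        model, _ = cal.fit_calibration(data, "linear")
        lim = cal.detection_limits(model, data)
        sd_b = blanks.std(ddof=1)
        b0, b1 = model.params["beta"]
        expected_lob = (0.0 + 1.645 * sd_b - b0) / b1
        assert lim.lob == pytest.approx(expected_lob, rel=1e-9)
        assert lim.lob <= lim.lod <= lim.loq

    def test_zero_blank_sd_collapses_all_limits(self):
        x = np.r_[0.0, 0.0, 1.0, 2.0, 4.0]
        y = np.r_[0.1, 0.1, 1.1, 2.1, 4.1]  # exact line, blank sd = 0
        data = cal.CalibrationData(x, y)
        model, _ = cal.fit_calibration(data, "linear")
        lim = cal.detection_limits(model, data)
        c_blank = model.inverse(0.1)[0]
        for v in (lim.lob, lim.lod, lim.loq):
            assert v == pytest.approx(c_blank, abs=1e-9)

    def test_ordering_on_randomized_calibrations(self):
        violations = 0
        for seed in range(100):
            data = simulate_line(seed=seed, sigma=0.05)
            model, _ = cal.fit_calibration(data, "linear")
            try:
                lim = cal.detection_limits(model, data)
            except cal.MonotonicityError:
                continue
            finite = [v for v in (lim.lob, lim.lod, lim.loq) if np.isfinite(v)]
            if sorted(finite) != finite:
                violations += 1
        assert violations == 0

    def test_decreasing_curve_limits_follow_direction(self):
        rng = np.random.default_rng(5)
        x = np.repeat(np.arange(8, dtype=float), 3)
        y = 5.0 - x + rng.normal(0, 0.05, x.size)
        data = cal.CalibrationData(x, y)
        model, _ = cal.fit_calibration(data, "linear")
        assert model.monotone_direction == -1
        lim = cal.detection_limits(model, data)
        assert 0 < lim.lob <= lim.lod <= lim.loq

    def test_no_blanks_unavailable(self):
        data = cal.CalibrationData([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        model, _ = cal.fit_calibration(data, "linear")
        with pytest.raises(cal.LimitsUnavailableError):
            cal.detection_limits(model, data)


class TestPersistence:
    def test_linear_round_trip_identical_coefficients(self, exact_line, tmp_path):
        model, _ = cal.fit_calibration(exact_line, "linear")
        path = tmp_path / "m.json"
        cal.save_model(model, path)
        back = cal.load_model(path)
        assert back.params["beta"] == model.params["beta"]
        assert back.x_range == model.x_range

    @pytest.mark.parametrize("kind", ["local_poly", "spline_additive"])
    def test_smoother_round_trip_predictions(self, kind, tmp_path):
        data = simulate_line(seed=3, sigma=0.02)
        model, _ = cal.fit_calibration(data, kind)
        path = tmp_path / "m.json"
        cal.save_model(model, path)
        back = cal.load_model(path)
        grid = np.linspace(*model.x_range, 100)
        np.testing.assert_allclose(back.predict(grid), model.predict(grid),
                                   atol=1e-9)

    def test_truncated_file_is_format_error(self, tmp_path, exact_line):
        model, _ = cal.fit_calibration(exact_line, "linear")
        path = tmp_path / "m.json"
        cal.save_model(model, path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(cal.ModelFormatError):
            cal.load_model(path)

    def test_version_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"version": 99, "kind": "linear"}')
        with pytest.raises(cal.ModelFormatError):
            cal.load_model(path)


class TestReport:
    def test_exact_line_report_content(self, tmp_path):
        x = np.r_[0.0, 0.0, 1, 2, 3]
        data = cal.CalibrationData(x, 0.5 + 2.0 * x)
        defn = cal.ResponseDefinition("tl/cl")
        model, metrics = cal.fit_calibration(data, "linear",
                                             {"response": defn})
        out = tmp_path / "report.md"
        cal.calibration_report(model, metrics, data, out,
                               settings={"method": "otsu"})
        text = out.read_text()
        assert "R² = 1" in text
        assert "LOB" in text and "LOD" in text and "LOQ" in text
        assert "tl/cl" in text
        assert "method: otsu" in text
        assert (tmp_path / "report.png").exists()

    def test_report_regeneration_is_deterministic(self, tmp_path, exact_line):
        model, metrics = cal.fit_calibration(exact_line, "linear")
        a, b = tmp_path / "a.md", tmp_path / "b.md"
        cal.calibration_report(model, metrics, exact_line, a)
        cal.calibration_report(model, metrics, exact_line, b)
        assert a.read_text().replace("a.png", "x.png") == \
            b.read_text().replace("b.png", "x.png")
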