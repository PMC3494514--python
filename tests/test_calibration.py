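"""Calibration-curve fitting, model selection and inverse prediction."""

import numpy as np
import pytest

from lcquant.calibration import (FAMILIES, MIN_STANDARDS, PARAM_COUNT,
                                 CalibrationCurve, StandardLevel,
                                 fit_calibration, invert, normalize_is,
                                 suggest_best_fit)
from lcquant.errors import (DomainError, FitError, InversionError,
                            NormalizationError)

#: Ground-truth coefficient sets used to generate standards per family.
TRUTH = {
    "linear": (50.0, 120.0),
    "logarithmic": (200.0, 85.0),
    "power": (2.0, 1.5),
    "exponential": (3.0, 1.4),
    "quadratic": (10.0, 40.0, 2.5),
    "cubic": (5.0, 30.0, 1.5, 0.08),
}

GRID = np.linspace(1.0, 10.0, 20)


def _curve(family, coeffs, c_min=1.0, c_max=10.0):
    padded = tuple(coeffs) + (0.0,) * (4 - len(coeffs))
    return CalibrationCurve(family=family, a0=padded[0], a1=padded[1],
                            a2=padded[2], a3=padded[3],
                            c_min=c_min, c_max=c_max, n_standards=6)


def _standards(family, coeffs, concentrations, noise=0.0, seed=0):
    curve = _curve(family, coeffs)
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        a = curve.predict(float(c))
        if noise:
            a *= 1.0 + rng.normal(0.0, noise)
        out.append(StandardLevel(concentration=float(c), area=float(a)))
    return out


class TestNormalizeIs:
    def test_ratio(self):
        assert normalize_is(1000.0, 500.0) == 2.0

    def test_zero_analyte(self):
        assert normalize_is(0.0, 500.0) == 0.0

    def test_zero_is_area_rejected(self):
        with pytest.raises(NormalizationError, match="run7"):
            normalize_is(1000.0, 0.0, run_id="run7")


class TestFitCalibration:
    def test_exact_line(self):
        stds = [StandardLevel(c, 10.0 * c) for c in (1.0, 2.0, 3.0)]
        curve = fit_calibration("linear", stds)
        assert curve.a0 == pytest.approx(0.0, abs=1e-9)
        assert curve.a1 == pytest.approx(10.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_power_log_linearization(self):
        # areas generated from A = 2 * C^1.5
        stds = _standards("power", (2.0, 1.5), [1, 2, 4, 8])
        curve = fit_calibration("power", stds)
        assert curve.a0 == pytest.approx(2.0, rel=1e-6)
        assert curve.a1 == pytest.approx(1.5, rel=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_needs_three_standards(self):
        stds = [StandardLevel(1.0, 5.0), StandardLevel(2.0, 9.0)]
        with pytest.raises(FitError):
            fit_calibration("quadratic", stds)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_minimum_standards_enforced(self, family):
        need = MIN_STANDARDS[family]
        concentrations = np.linspace(1.0, 10.0, need - 1)
        stds = _standards(family, TRUTH[family], concentrations)
        with pytest.raises(FitError):
            fit_calibration(family, stds)
        # the stated minimum fits
        fit_calibration(family, _standards(
            family, TRUTH[family], np.linspace(1.0, 10.0, need)))

    def test_nonpositive_concentration_rejected_for_log(self):
        stds = [StandardLevel(0.0, 1.0), StandardLevel(1.0, 2.0),
                StandardLevel(2.0, 3.0)]
        with pytest.raises(DomainError):
            fit_calibration("logarithmic", stds)

    def test_duplicate_concentrations_collapse_rank(self):
        stds = [StandardLevel(2.0, 10.0), StandardLevel(2.0, 10.5),
                StandardLevel(2.0, 9.5)]
        with pytest.raises(FitError):
            fit_calibration("linear", stds)

    def test_replicates_are_pooled(self):
        stds = [StandardLevel(c, 10.0 * c)
                for c in (1.0, 1.0, 2.0, 2.0, 3.0)]
        curve = fit_calibration("linear", stds)
        assert curve.a1 == pytest.approx(10.0)
        assert curve.n_standards == 5

    @pytest.mark.parametrize("family", FAMILIES)
    def test_noise_free_parameter_recovery(self, family):
        concentrations = np.linspace(1.0, 10.0, 6)
        stds = _standards(family, TRUTH[family], concentrations)
        curve = fit_calibration(family, stds)
        np.testing.assert_allclose(curve.coefficients, TRUTH[family],
                                   rtol=1e-6, atol=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("family", ["logarithmic", "power",
                                        "exponential"])
    def test_parameter_recovery_under_noise(self, family):
        # 2% multiplicative noise, six standards, fixed seed; the
        # two-parameter families are well identified from a single draw
        concentrations = np.linspace(1.0, 10.0, 6)
        stds = _standards(family, TRUTH[family], concentrations,
                          noise=0.02, seed=2024)
        curve = fit_calibration(family, stds)
        np.testing.assert_allclose(curve.coefficients, TRUTH[family],
                                   rtol=0.10)

    @pytest.mark.parametrize("family,truth", [
        ("linear", (50.0, 120.0)),
        ("quadratic", (50.0, 30.0, 2.0)),
        ("cubic", (90.0, 150.0, 20.0, 0.3)),
    ])
    def test_polynomial_recovery_under_noise(self, family, truth):
        # polynomial bases are collinear on a six-point design, so single
        # draws cannot pin every coefficient to 10%; the median estimate
        # over seeded replicates can, and checks recovery (unbiasedness)
        concentrations = np.geomspace(0.1, 100.0, 6)
        estimates = [
            fit_calibration(family, _standards(family, truth,
                                               concentrations,
                                               noise=0.02,
                                               seed=s)).coefficients
            for s in range(11)]
        median = np.median(np.array(estimates), axis=0)
        np.testing.assert_allclose(median, truth, rtol=0.10)

    def test_scale_equivariance_matches_is_normalization(self):
        # constant-IS normalization rescales areas; linear-in-parameter
        # families scale their coefficients by the same factor
        concentrations = np.linspace(1.0, 10.0, 6)
        for family in ("linear", "logarithmic", "quadratic", "cubic"):
            stds = _standards(family, TRUTH[family], concentrations)
            scaled = [StandardLevel(s.concentration,
                                    normalize_is(s.area, 4.0))
                      for s in stds]
            raw = fit_calibration(family, stds)
            norm = fit_calibration(family, scaled, is_normalized=True)
            np.testing.assert_allclose(
                np.array(norm.coefficients) * 4.0, raw.coefficients,
                rtol=1e-9, atol=1e-9)
            assert norm.is_normalized

    def test_inverse_weighting_accepted(self):
        stds = _standards("linear", TRUTH["linear"],
                          np.linspace(1.0, 10.0, 6), noise=0.02, seed=5)
        for w in ("1/C", "1/C2"):
            curve = fit_calibration("linear", stds, weighting=w)
            assert curve.a1 == pytest.approx(TRUTH["linear"][1], rel=0.1)


class TestSuggestBestFit:
    def test_parsimony_on_perfectly_linear_standards(self):
        stds = [StandardLevel(c, 10.0 * c) for c in np.linspace(1, 10, 6)]
        curves = [fit_calibration(f, stds)
                  for f in ("linear", "quadratic", "cubic")]
        assert suggest_best_fit(curves) == "linear"

    def test_exponential_truth_wins(self):
        stds = _standards("exponential", (3.0, 1.4), np.linspace(1, 10, 6))
        curves = [fit_calibration(f, stds) for f in FAMILIES]
        exp_r2 = next(c.r_squared for c in curves
                      if c.family == "exponential")
        for c in curves:
            if c.family != "exponential":
                assert exp_r2 > c.r_squared
        assert suggest_best_fit(curves) == "exponential"

    def test_single_curve_returned(self):
        stds = _standards("power", (2.0, 1.5), [1, 2, 4, 8])
        curve = fit_calibration("power", stds)
        assert suggest_best_fit([curve]) == "power"

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            suggest_best_fit([])


class TestInvert:
    def test_linear_closed_form(self):
        curve = _curve("linear", (0.0, 10.0), c_min=1.0, c_max=10.0)
        conc, extrapolated = invert(curve, 50.0)
        assert conc == pytest.approx(5.0)
        assert not extrapolated

    @pytest.mark.parametrize("family", FAMILIES)
    def test_round_trip_on_grid(self, family):
        curve = _curve(family, TRUTH[family])
        for c in GRID:
            conc, extrapolated = invert(curve, curve.predict(float(c)))
            assert conc == pytest.approx(float(c), abs=1e-6)
            assert not extrapolated

    def test_quadratic_root_selection(self):
        # A = C^2, range [1, 10]: area 25 must give the in-range root +5
        curve = _curve("quadratic", (0.0, 0.0, 1.0), c_min=1.0, c_max=10.0)
        conc, extrapolated = invert(curve, 25.0)
        assert conc == pytest.approx(5.0)
        assert not extrapolated

    def test_extrapolation_flagged(self):
        curve = _curve("linear", (0.0, 10.0), c_min=1.0, c_max=10.0)
        conc, extrapolated = invert(curve, 150.0)
        assert conc == pytest.approx(15.0)
        assert extrapolated

    def test_flat_curve_rejected(self):
        with pytest.raises(InversionError):
            invert(_curve("linear", (5.0, 0.0)), 5.0)

    def test_negative_area_rejected_for_power(self):
        with pytest.raises(DomainError):
            invert(_curve("power", (2.0, 1.5)), -1.0)

    def test_quadratic_without_real_root_rejected(self):
        curve = _curve("quadratic", (100.0, 0.0, 1.0))
        with pytest.raises(InversionError):
            invert(curve, 50.0)


def test_r_squared_is_one_only_on_family_members():
    concentrations = np.linspace(1.0, 10.0, 6)
    on_curve = _standards("linear", (5.0, 7.0), concentrations)
    off_curve = _standards("linear", (5.0, 7.0), concentrations,
                           noise=0.05, seed=1)
    assert fit_calibration("linear", on_curve).r_squared \
        == pytest.approx(1.0, abs=1e-12)
    assert fit_calibration("linear", off_curve).r_squared < 1.0 - 1e-9
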