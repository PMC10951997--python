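import numpy as np
import pytest

from oslet.osl_model import (
    CalIrradiation,
    DoseCal,
    EfficiencyCurve,
    NoiseConfig,
    RatioCurve,
    ResponseModel,
    SaturationError,
    efficiency,
    fit_calibrations,
    forward_readout_point,
    invert_ratio,
    reference_normalize,
    simulate_calibration_irradiations,
    uv_blue_ratio,
)


class TestEfficiency:
    def test_unity_at_reference_quality(self):
        c = EfficiencyCurve()
        assert efficiency(c, c.l_ref) == pytest.approx(1.0, abs=1e-15)

    def test_strictly_decreasing(self):
        c = EfficiencyCurve()
        L = np.linspace(0.5, 41.3, 200)
        eta = efficiency(c, L)
        assert np.all(np.diff(eta) < 0)
        assert np.all(eta > 0)

    def test_quenching_correction_below_ten_percent_in_sobp(self):
        """1/eta stays below 1.10 across proton SOBP LET values (<= 6 keV/um)."""
        c = EfficiencyCurve()
        assert efficiency(c, 6.0) == pytest.approx(0.93, abs=0.005)
        L = np.linspace(0.5, 6.0, 50)
        assert np.all(1.0 / efficiency(c, L) <= 1.10)

    def test_closed_form(self):
        c = EfficiencyCurve()
        for L in range(1, 7):
            expected = (1 + c.a * c.l_ref) / (1 + c.a * L)
            assert efficiency(c, float(L)) == pytest.approx(expected, rel=1e-14)

    def test_domain_rejection(self):
        c = EfficiencyCurve()
        with pytest.raises(SaturationError):
            efficiency(c, 0.0)
        with pytest.raises(SaturationError):
            efficiency(c, 41.4)


class TestRatioCurve:
    def test_roundtrip_inversion(self):
        c = RatioCurve()
        assert invert_ratio(c, float(uv_blue_ratio(c, 3.0))) == pytest.approx(3.0, abs=1e-6)

    def test_strictly_increasing(self):
        c = RatioCurve()
        r = uv_blue_ratio(c, np.linspace(0.1, 41.3, 100))
        assert np.all(np.diff(r) > 0)

    def test_inversion_matches_grid_lookup(self):
        """Root finding agrees with an exhaustive 10^4-point grid lookup."""
        c = RatioCurve()
        grid = np.linspace(1e-3, 41.3, 10_000)
        rg = uv_blue_ratio(c, grid)
        for target in (0.8, 2.0, 5.0, 9.0):
            r_t = float(uv_blue_ratio(c, target))
            expected = grid[np.argmin(np.abs(rg - r_t))]
            got = invert_ratio(c, r_t)
            assert abs(got - expected) <= grid[1] - grid[0]

    def test_out_of_image_rejected(self):
        c = RatioCurve()
        with pytest.raises(SaturationError):
            invert_ratio(c, 1e9)
        with pytest.raises(SaturationError):
            invert_ratio(c, 0.0)

    def test_log_slope_matches_finite_difference(self):
        c = RatioCurve()
        for L in (1.0, 3.0, 10.0):
            h = 1e-6 * L
            fd = (np.log(uv_blue_ratio(c, L + h)) - np.log(uv_blue_ratio(c, L - h))) / (
                np.log(L + h) - np.log(L - h))
            assert c.log_slope(L) == pytest.approx(float(fd), rel=1e-6)


class TestForwardReadout:
    def test_linear_chain_without_quenching(self):
        """Noise off, eta == 1, zero intercept: blue/ref_blue * ref_dose = D."""
        model = ResponseModel(dose_cal=DoseCal(slope=500.0, intercept=0.0),
                              efficiency=EfficiencyCurve(a=0.0))
        rng = np.random.default_rng(0)
        ro = forward_readout_point("d", 1.5, 3.0, model, NoiseConfig(enabled=False), rng)
        assert ro.blue / ro.ref_blue * ro.ref_dose == pytest.approx(1.5, rel=1e-12)

    def test_ratio_exact_without_noise(self):
        model = ResponseModel()
        rng = np.random.default_rng(0)
        ro = forward_readout_point("d", 1.5, 3.0, model, NoiseConfig(enabled=False), rng)
        assert ro.uv / ro.blue == pytest.approx(float(uv_blue_ratio(model.ratio, 3.0)), rel=1e-12)

    def test_ratio_precision_below_stated_bound(self):
        """Relative SD of uv/blue across 200 noisy readouts stays below 0.6%:
        the sensitivity factor cancels in the band ratio."""
        model = ResponseModel()
        rng = np.random.default_rng(12345)
        ratios = [
            (lambda ro: ro.uv / ro.blue)(
                forward_readout_point("d", 1.82, 3.0, model, NoiseConfig(), rng))
            for _ in range(200)
        ]
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() * 100 < 0.6

    def test_out_of_domain_let_rejected(self):
        model = ResponseModel()
        with pytest.raises(SaturationError):
            forward_readout_point("d", 1.0, 50.0, model, NoiseConfig(enabled=False),
                                  np.random.default_rng(0))


class TestReferenceNormalize:
    def test_sensitivity_cancels(self):
        model = ResponseModel()
        rng = np.random.default_rng(0)
        ro1 = forward_readout_point("a", 1.5, 1.0, model, NoiseConfig(enabled=False),
                                    rng, sensitivity=0.9)
        ro2 = forward_readout_point("b", 1.5, 1.0, model, NoiseConfig(enabled=False),
                                    rng, sensitivity=1.1)
        assert ro1.blue != ro2.blue
        assert reference_normalize(ro1) == pytest.approx(reference_normalize(ro2), rel=1e-12)

    def test_unit_reference(self):
        from oslet.osl_model import OsldReadout

        ro = OsldReadout("d", blue=123.0, uv=50.0, ref_blue=123.0, ref_dose=1.0)
        assert reference_normalize(ro) == pytest.approx(1.0 * 123.0 / 123.0)

    def test_population_spread_suppressed(self):
        """50 detectors with 3% sensitivity spread: normalized blue spreads
        by well under 1%."""
        model = ResponseModel()
        rng = np.random.default_rng(7)
        vals = [reference_normalize(
            forward_readout_point(f"d{i}", 2.0, model.efficiency.l_ref, model,
                                  NoiseConfig(), rng)) for i in range(50)]
        vals = np.array(vals)
        raw = [forward_readout_point(f"r{i}", 2.0, model.efficiency.l_ref, model,
                                     NoiseConfig(), rng).blue for i in range(50)]
        raw = np.array(raw)
        assert vals.std() / vals.mean() < 0.01
        assert raw.std() / raw.mean() > 0.02  # the spread existed before normalizing


class TestFitCalibrations:
    def test_noise_free_recovery_is_exact(self):
        model = ResponseModel()
        rng = np.random.default_rng(0)
        cals = fit_calibrations(simulate_calibration_irradiations(
            model, NoiseConfig(enabled=False), rng))
        # normalized-scale slope: slope*ref/(slope*ref + intercept)
        dc = model.dose_cal
        expected_slope = dc.slope * 1.0 / dc.signal(1.0)
        assert cals.dose_cal.slope == pytest.approx(expected_slope, rel=1e-6)
        assert cals.ratio.r0 == pytest.approx(model.ratio.r0, rel=1e-6)
        assert cals.ratio.c == pytest.approx(model.ratio.c, rel=1e-5)
        assert cals.efficiency.a == pytest.approx(model.efficiency.a, rel=1e-5)

    def test_dose_residual_sd_below_one_percent(self):
        model = ResponseModel()
        rng = np.random.default_rng(11)
        sds = []
        for _ in range(20):
            cals = fit_calibrations(simulate_calibration_irradiations(model, NoiseConfig(), rng))
            sds.append(cals.residual_sd_pct["dose_pct"])
        assert np.median(sds) < 1.0

    def test_too_few_points_rejected(self):
        model = ResponseModel()
        rng = np.random.default_rng(0)
        cal = simulate_calibration_irradiations(model, NoiseConfig(enabled=False), rng,
                                                doses=np.linspace(0.5, 5, 6))
        few = [c for c in cal if c.series == "let"][:3] + [c for c in cal if c.series == "dose"]
        with pytest.raises(ValueError):
            fit_calibrations(few)

    def test_nonlinear_domain_rejected(self):
        model = ResponseModel()
        rng = np.random.default_rng(0)
        cal = simulate_calibration_irradiations(model, NoiseConfig(enabled=False), rng,
                                                doses=np.linspace(1.0, 8.0, 8))
        with pytest.raises(ValueError, match="linear"):
            fit_calibrations(cal)
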