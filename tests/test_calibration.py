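"""Pixel-to-wavelength mapping, per-wavelength OLS calibration, LOLO validation."""

import numpy as np
import pytest
from scipy import stats

from aquarad.calibration import (
    PerWavelengthLinearCalibrator,
    PixelSpectrum,
    WavelengthPolynomial,
    apply_calibration,
    fit_calibration,
    leave_one_location_out,
    pixel_to_wavelength,
)
from aquarad.errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyFitError,
    GridMismatchError,
)
from aquarad.spectra import DEFAULT_GRID, Spectrum, Unit, WavelengthGrid
from aquarad.synthetic import (
    EnvironmentModels,
    SceneParams,
    default_instrument,
    forward_model_station,
    generate_campaign,
)


class TestPixelToWavelength:
    def test_affine_polynomial_maps_directly(self):
        poly = WavelengthPolynomial((300.0, 2.0, 0.0, 0.0, 0.0, 0.0))
        px = PixelSpectrum(np.array([10.0, 20.0, 30.0]))
        s = pixel_to_wavelength(px, poly)
        assert np.array_equal(s.wavelengths, [300.0, 302.0, 304.0])
        assert s.unit is Unit.COUNTS_AU

    def test_all_pixels_at_ceiling_all_masked(self):
        poly = WavelengthPolynomial((300.0, 2.0))
        px = PixelSpectrum(np.full(5, 1000.0), saturation_ceiling=1000.0)
        s = pixel_to_wavelength(px, poly)
        assert s.effective_mask().all()

    def test_full_degree5_matches_horner_evaluation(self):
        coeffs = (310.0, 1.9, 3e-4, -2e-7, 5e-11, -1e-14)
        poly = WavelengthPolynomial(coeffs)
        p = 10.0
        horner = 0.0
        for c in reversed(coeffs):
            horner = horner * p + c
        assert poly(p) == pytest.approx(horner, rel=1e-15)

    def test_non_monotone_polynomial_rejected(self):
        poly = WavelengthPolynomial((300.0, -1.0))
        with pytest.raises(ConfigurationError):
            pixel_to_wavelength(PixelSpectrum(np.ones(5)), poly)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            PixelSpectrum(np.array([1.0, -2.0, 3.0]))


class TestPerWavelengthOLS:
    def test_matches_closed_form_oracle_to_machine_precision(self, rng):
        # oracle: scipy.stats.linregress column by column
        X = rng.uniform(100, 5000, size=(12, 7))
        Y = 0.002 * X + 0.3 + rng.normal(0, 0.05, size=X.shape)
        est = PerWavelengthLinearCalibrator().fit(X, Y)
        for j in range(X.shape[1]):
            lr = stats.linregress(X[:, j], Y[:, j])
            assert est.gain_[j] == pytest.approx(lr.slope, rel=1e-12)
            assert est.offset_[j] == pytest.approx(lr.intercept, rel=1e-12)
            assert est.r2_[j] == pytest.approx(lr.rvalue**2, rel=1e-10)

    def test_noiseless_recovery_is_exact_with_unit_r2(self, rng):
        X = rng.uniform(100, 5000, size=(8, 5))
        gain = np.array([1e-3, 2e-3, 3e-3, 4e-3, 5e-3])
        offset = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        est = PerWavelengthLinearCalibrator().fit(X, gain * X + offset)
        np.testing.assert_allclose(est.gain_, gain, rtol=1e-12)
        np.testing.assert_allclose(est.offset_, offset, rtol=1e-10)
        np.testing.assert_allclose(est.r2_, 1.0, atol=1e-12)

    def test_nan_pairs_excluded_pairwise(self, rng):
        X = rng.uniform(1, 10, size=(6, 2))
        Y = 2.0 * X + 1.0
        X[0, 0] = np.nan
        Y[1, 0] = np.nan
        est = PerWavelengthLinearCalibrator().fit(X, Y)
        assert est.n_used_[0] == 4 and est.n_used_[1] == 6
        np.testing.assert_allclose(est.gain_, 2.0, rtol=1e-12)

    def test_all_columns_unusable_raises(self):
        X = np.full((3, 2), np.nan)
        with pytest.raises(EmptyFitError):
            PerWavelengthLinearCalibrator().fit(X, X)

    def test_sklearn_params_roundtrip(self):
        est = PerWavelengthLinearCalibrator(fit_intercept=False)
        assert est.get_params() == {"fit_intercept": False}
        est.set_params(fit_intercept=True)
        assert est.fit_intercept


class TestFitCalibration:
    def test_noiseless_campaign_recovers_true_gain(self, noiseless_campaign,
                                                   noiseless_instrument):
        cal = fit_calibration(noiseless_campaign, "Lsky", DEFAULT_GRID)
        true_gain = noiseless_instrument.gain_at(DEFAULT_GRID.wavelengths())
        np.testing.assert_allclose(cal.gain, true_gain, rtol=1e-9)
        np.testing.assert_allclose(cal.fit_r2, 1.0, atol=1e-9)

    def test_noisy_gain_within_two_percent(self):
        # 30 stations spanning a wide illumination range at 1% multiplicative
        # noise: every per-wavelength gain estimate lands within +/-2% of truth
        inst = default_instrument(noise_sd_fraction=0.01)
        rng = np.random.default_rng(101)
        recs = [
            forward_model_station(SceneParams(seed=k), inst,
                                  EnvironmentModels(brightness=b),
                                  site_id=f"s{k}", rng=rng)
            for k, b in enumerate(np.linspace(0.4, 1.6, 30))
        ]
        cal = fit_calibration(recs, "Lsky", DEFAULT_GRID)
        true_gain = inst.gain_at(DEFAULT_GRID.wavelengths())
        rel = np.abs(cal.gain - true_gain) / true_gain
        assert np.nanmax(rel) < 0.02

    def test_saturated_window_excluded_and_masked(self):
        # drive the panel channel into saturation over a wavelength window;
        # those wavelengths must be masked, and the clipped (poisoned)
        # values must not influence neighbouring fits
        inst_sat = default_instrument(noise_sd_fraction=0.0,
                                      saturation_ceiling=17000.0)
        recs = [
            forward_model_station(SceneParams(seed=s), inst_sat,
                                  EnvironmentModels(brightness=b),
                                  site_id=f"s{s}")
            for s, b in zip(range(4), (0.9, 1.0, 1.1, 1.2))
        ]
        assert any(r.device["Lc"].mask is not None for r in recs)
        cal = fit_calibration(recs, "Lc", DEFAULT_GRID)
        wl = DEFAULT_GRID.wavelengths()
        sat_mask = cal.effective_mask()
        assert sat_mask.any()
        # unmasked wavelengths still recover the true gain exactly: clipping
        # never leaked into the fit
        inst = default_instrument(noise_sd_fraction=0.0)
        ok = ~sat_mask
        np.testing.assert_allclose(cal.gain[ok], inst.gain_at(wl)[ok], rtol=1e-9)

    def test_requires_two_records(self, noiseless_campaign):
        with pytest.raises(DegenerateInputError):
            fit_calibration(noiseless_campaign[:1], "Lw")

    def test_integration_time_normalisation(self, rng):
        # same scene recorded at two integration times: counts scale linearly,
        # so normalisation recovers a single consistent gain
        base = default_instrument(noise_sd_fraction=0.0)
        recs = []
        for i, t in enumerate((10.0, 10.0, 20.0, 20.0)):
            rec = forward_model_station(
                SceneParams(seed=i), base, EnvironmentModels(brightness=0.8 + 0.1 * i),
                site_id=f"s{i}")
            for comp in rec.device:
                d = rec.device[comp]
                scale = t / 10.0
                rec.device[comp] = d.replace(values=d.values * scale,
                                             meta={**d.meta,
                                                   "integration_time_ms": t})
            recs.append(rec)
        cal = fit_calibration(recs, "Lsky", DEFAULT_GRID)
        assert np.all(np.isfinite(cal.gain))
        np.testing.assert_allclose(cal.fit_r2, 1.0, atol=1e-9)


class TestApplyCalibration:
    def test_identity_gain_zero_offset(self, noiseless_campaign):
        cal = fit_calibration(noiseless_campaign, "Lw", DEFAULT_GRID)
        cal.gain[:] = 1.0
        cal.offset[:] = 0.0
        wl = DEFAULT_GRID.wavelengths()
        s = Spectrum(wl, np.linspace(1, 2, wl.size), "counts_AU")
        out = apply_calibration(s, cal)
        assert np.array_equal(out.values, s.values)
        assert out.unit is Unit.RADIANCE

    def test_zero_counts_returns_offset(self, noiseless_campaign):
        cal = fit_calibration(noiseless_campaign, "Lw", DEFAULT_GRID)
        wl = DEFAULT_GRID.wavelengths()
        out = apply_calibration(Spectrum(wl, np.zeros(wl.size), "counts_AU"), cal)
        np.testing.assert_array_equal(out.values, cal.offset)

    def test_fit_apply_round_trip_self_consistent(self, noiseless_campaign):
        cal = fit_calibration(noiseless_campaign, "Lsky", DEFAULT_GRID)
        # refit on (counts, calibrated radiance) pairs gives the same line
        from aquarad.spectra import resample
        X = np.vstack([resample(r.device["Lsky"], DEFAULT_GRID).masked_values()
                       for r in noiseless_campaign])
        Y = cal.gain * X + cal.offset
        est = PerWavelengthLinearCalibrator().fit(X, Y)
        np.testing.assert_allclose(est.gain_, cal.gain, rtol=1e-9)
        np.testing.assert_allclose(est.offset_, cal.offset, rtol=1e-6, atol=1e-12)

    def test_grid_mismatch_rejected(self, noiseless_campaign):
        cal = fit_calibration(noiseless_campaign, "Lw", DEFAULT_GRID)
        other = WavelengthGrid(400, 800, 1).wavelengths()
        s = Spectrum(other, np.ones(other.size), "counts_AU")
        with pytest.raises(GridMismatchError):
            apply_calibration(s, cal)


class TestLeaveOneLocationOut:
    def test_noiseless_identity_at_every_held_out_site(self, noiseless_campaign):
        reports = leave_one_location_out(noiseless_campaign)
        assert len(reports) == 6
        for rep in reports.values():
            for key in ("Lw", "Lsky", "Lc", "Rrs"):
                r = rep.reports[key]
                assert r.r2 == pytest.approx(1.0, abs=1e-8)
                assert r.nrmse_pct == pytest.approx(0.0, abs=1e-8)

    def test_single_site_rejected(self, noiseless_campaign):
        one_site = [r for r in noiseless_campaign if r.site_id == "site1"]
        with pytest.raises(DegenerateInputError):
            leave_one_location_out(one_site)

    def test_anomalous_site_shows_largest_bias(self):
        # one site's device gain differs by a factor 2: its held-out bias
        # must dominate all other sites
        inst = default_instrument(noise_sd_fraction=0.0)
        bad_inst = default_instrument(noise_sd_fraction=0.0,
                                      gain=2.0 * inst.gain.copy())
        rng = np.random.default_rng(5)
        recs = []
        for s in range(6):
            use = bad_inst if s == 0 else inst
            for k in range(3):
                recs.append(forward_model_station(
                    SceneParams(chl_level=0.5, pc_level=0.5,
                                seed=int(rng.integers(2**31))),
                    use, EnvironmentModels(brightness=float(rng.uniform(0.8, 1.2))),
                    site_id=f"site{s + 1}", rng=rng))
        reports = leave_one_location_out(recs)
        biases = {site: abs(rep.reports["Lsky"].beta_pct)
                  for site, rep in reports.items()}
        assert max(biases, key=biases.get) == "site1"

    def test_two_identical_sites_transfer(self):
        # identical generating parameters at both sites: held-out error stays
        # at the noise floor
        inst = default_instrument(noise_sd_fraction=0.005)
        rng = np.random.default_rng(11)
        recs = []
        for s in range(2):
            for k in range(8):
                recs.append(forward_model_station(
                    SceneParams(chl_level=0.5, pc_level=0.5, seed=k),
                    inst, EnvironmentModels(brightness=0.8 + 0.05 * k),
                    site_id=f"site{s + 1}", rng=rng))
        reports = leave_one_location_out(recs)
        for rep in reports.values():
            assert rep.reports["Lsky"].r2 > 0.99
            assert rep.reports["Lsky"].nrmse_pct < 5.0
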