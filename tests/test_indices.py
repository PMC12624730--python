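"""Bloom index primitives: arithmetic oracles, invariances, monotone response."""

import numpy as np
import pytest
from scipy import stats

from aquarad.bands import BandSpectrum, builtin_band_set, to_band_spectrum
from aquarad.errors import ConfigurationError
from aquarad.indices import (
    IndexDefinition,
    SpectralIndexTransformer,
    compute_all_indices,
    default_index_definitions,
    fit_index_recalibration,
    normalized_difference,
    reciprocal_three_band,
    spectral_shape,
)
from aquarad.synthetic import SceneParams, generate_rrs

CENTERS = np.array([560.0, 620.0, 665.0, 681.0, 708.0])
LABELS = ["560", "620", "665", "681", "708"]


def bands(values, mask=None):
    return BandSpectrum("test", LABELS, CENTERS, np.asarray(values, float),
                        "rrs_per_sr", mask=mask)


class TestNormalizedDifference:
    def test_equal_bands_give_zero(self):
        b = bands([0.01, 0.01, 0.004, 0.01, 0.004])
        assert normalized_difference(b, 708, 665) == 0.0

    def test_direct_arithmetic(self):
        b = bands([0.01, 0.01, 0.002, 0.01, 0.004])
        assert normalized_difference(b, 708, 665) == pytest.approx(1.0 / 3.0,
                                                                   rel=1e-12)

    def test_boundary_minus_one(self):
        b = bands([0.01, 0.01, 0.002, 0.01, 0.0])
        assert normalized_difference(b, 708, 665) == -1.0

    def test_bounded_for_positive_bands(self, rng):
        for _ in range(50):
            b = bands(rng.uniform(1e-5, 0.05, 5))
            v = normalized_difference(b, 708, 665)
            assert -1.0 <= v <= 1.0

    def test_zero_denominator_is_nan_not_exception(self):
        b = bands([0.01, 0.01, 0.0, 0.01, 0.0])
        assert np.isnan(normalized_difference(b, 708, 665))


class TestReciprocalThreeBand:
    def test_equal_first_two_bands_give_zero(self):
        b = bands([0.01, 0.004, 0.004, 0.01, 0.123])
        assert reciprocal_three_band(b, 620, 665, 708) == 0.0

    def test_direct_arithmetic(self):
        # (1/0.002 - 1/0.004) * 0.004 = (500 - 250) * 0.004 = 1.0
        b = bands([0.01, 0.002, 0.004, 0.01, 0.004])
        assert reciprocal_three_band(b, 620, 665, 708) == pytest.approx(1.0,
                                                                        rel=1e-12)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(1e-3, 0.05, 5)
        for c in (0.1, 3.0, 100.0):
            v0 = reciprocal_three_band(bands(vals), 620, 665, 708)
            vc = reciprocal_three_band(bands(c * vals), 620, 665, 708)
            assert vc == pytest.approx(v0, rel=1e-10)

    def test_zero_band_is_nan(self):
        b = bands([0.01, 0.0, 0.004, 0.01, 0.004])
        assert np.isnan(reciprocal_three_band(b, 620, 665, 708))


class TestSpectralShape:
    def test_affine_spectrum_gives_zero(self):
        vals = 0.001 + 1e-5 * CENTERS  # affine in wavelength
        assert spectral_shape(bands(vals), 681, 665, 708) == pytest.approx(
            0.0, abs=1e-18)
        assert spectral_shape(bands(vals), 620, 560, 665) == pytest.approx(
            0.0, abs=1e-18)

    def test_direct_arithmetic(self):
        # baseline at 620 between (560, 665) with equal endpoints is flat:
        # SS = 0.002 - 0.004 = -0.002
        b = bands([0.004, 0.002, 0.004, 0.01, 0.01])
        assert spectral_shape(b, 620, 560, 665) == pytest.approx(-0.002,
                                                                 rel=1e-12)
        assert spectral_shape(b, 620, 560, 665, sign=-1.0) == pytest.approx(
            0.002, rel=1e-12)

    def test_offset_invariance(self, rng):
        vals = rng.uniform(1e-3, 0.05, 5)
        v0 = spectral_shape(bands(vals), 681, 665, 708)
        v1 = spectral_shape(bands(vals + 0.37), 681, 665, 708)
        assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-15)

    def test_uses_actual_band_centers(self):
        # OLCI's 681.25/708.75 centers enter the baseline wavelength ratio
        olci = builtin_band_set("olci")
        b = BandSpectrum("olci", olci.labels, olci.centers,
                         np.array([0.004, 0.003, 0.002, 0.004, 0.006]),
                         "rrs_per_sr")
        rc, rl, rr = 0.004, 0.002, 0.006
        lc, ll, lr = 681.25, 665.0, 708.75
        expected = rc - rl - (rr - rl) * (lc - ll) / (lr - ll)
        assert spectral_shape(b, 681, 665, 708) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_degenerate_flanks_rejected(self):
        with pytest.raises(ConfigurationError):
            spectral_shape(bands([1, 2, 3, 4, 5]), 620, 665, 665)


class TestComputeAllIndices:
    def test_flat_band_spectrum_all_zero(self):
        out = compute_all_indices(bands(np.full(5, 0.01)))
        assert set(out) == {"NDCI", "PC3", "CI", "PCI"}
        for v in out.values():
            assert v == pytest.approx(0.0, abs=1e-15)

    def test_bloom_spectrum_default_sign_directions(self):
        # 620 dip + 665 dip + 708 peak: NDCI, CI, PCI positive under default
        # signs; PC3 sits below its no-bloom value when phycocyanin deepens
        band_set = builtin_band_set("pace_oci")
        sc = SceneParams(chl_level=0.9, pc_level=0.9, seed=3)
        out = compute_all_indices(to_band_spectrum(generate_rrs(sc), band_set))
        assert out["NDCI"] > 0 and out["CI"] > 0 and out["PCI"] > 0
        pc_only = {
            lvl: compute_all_indices(to_band_spectrum(
                generate_rrs(SceneParams(chl_level=0.0, pc_level=lvl, seed=3)),
                band_set))["PC3"]
            for lvl in (0.0, 0.9)
        }
        assert pc_only[0.9] < pc_only[0.0]

    def test_masked_band_masks_dependent_indices_only(self):
        mask = np.array([False, False, False, True, False])  # 681 masked
        out = compute_all_indices(bands(np.full(5, 0.01), mask=mask))
        assert np.isnan(out["CI"])
        assert np.isfinite(out["NDCI"]) and np.isfinite(out["PCI"])

    def test_missing_band_warns_and_masks(self):
        three = BandSpectrum("t", ["620", "665", "708"],
                             np.array([620.0, 665.0, 708.0]),
                             np.full(3, 0.01), "rrs_per_sr")
        with pytest.warns(UserWarning):
            out = compute_all_indices(three)
        assert np.isnan(out["PCI"])  # needs 560
        assert np.isfinite(out["NDCI"])


@pytest.mark.parametrize("sensor", ["pace_oci", "olci"])
@pytest.mark.parametrize(
    "index_name,param,expected_rho",
    [
        ("NDCI", "chl_level", 1.0),
        ("CI", "chl_level", 1.0),
        ("PCI", "pc_level", 1.0),
        ("PC3", "pc_level", -1.0),
    ],
)
def test_monotone_response_to_pigment_parameter(sensor, index_name, param,
                                                expected_rho):
    """Ten-point sweep of the generator pigment parameter: each index is
    perfectly monotone, in its documented direction."""
    band_set = builtin_band_set(sensor)
    levels = np.linspace(0.0, 1.0, 10)
    values = []
    for p in levels:
        kwargs = {"chl_level": 0.5, "pc_level": 0.5, "seed": 7, param: p}
        b = to_band_spectrum(generate_rrs(SceneParams(**kwargs)), band_set)
        values.append(compute_all_indices(b)[index_name])
    rho = stats.spearmanr(levels, values).statistic
    assert rho == pytest.approx(expected_rho, abs=1e-12)


class TestIndexDefinition:
    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError):
            IndexDefinition("X", "quadratic", {})

    def test_missing_role_rejected(self):
        with pytest.raises(ConfigurationError):
            IndexDefinition("X", "normalized_difference", {"plus": 708})

    def test_defaults_are_the_four_canonical_indices(self):
        names = [d.name for d in default_index_definitions()]
        assert names == ["NDCI", "PC3", "CI", "PCI"]


class TestTransformerAndRecalibration:
    def test_transformer_matches_function_path(self, rng):
        tr = SpectralIndexTransformer(band_centers=CENTERS,
                                      band_labels=LABELS).fit()
        rows = rng.uniform(0.001, 0.03, size=(5, 5))
        out = tr.transform(rows)
        for i in range(5):
            expected = compute_all_indices(bands(rows[i]))
            np.testing.assert_allclose(
                out[i], [expected[n] for n in ("NDCI", "PC3", "CI", "PCI")],
                rtol=1e-12)

    def test_vicarious_recalibration_recovers_linear_map(self, rng):
        ref = rng.uniform(-0.2, 0.6, 20)
        est = (ref - 0.05) / 1.2  # device systematically off
        slope, intercept = fit_index_recalibration(est, ref)
        assert slope == pytest.approx(1.2, rel=1e-9)
        assert intercept == pytest.approx(0.05, abs=1e-9)
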