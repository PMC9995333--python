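import numpy as np
import pytest

from floatpump import preprocess as pp
from floatpump import seawater as sw
from floatpump.constants import Constants

CONST = Constants()


class TestRegrid:
    def test_identity_on_1m_grid(self):
        z = np.arange(0.0, 100.0)
        v = np.sin(z / 10.0)
        out = pp.regrid_profile(z, v, z)
        np.testing.assert_allclose(out, v)

    def test_linear_midpoint(self):
        out = pp.regrid_profile([0.0, 10.0], [0.0, 10.0], np.arange(0.0, 11.0))
        assert out[5] == pytest.approx(5.0)

    def test_wide_gap_masked(self):
        z_raw = np.concatenate((np.arange(0.0, 51.0, 10.0), [90.0, 100.0]))
        v_raw = np.ones_like(z_raw)
        out = pp.regrid_profile(z_raw, v_raw, np.arange(0.0, 101.0), max_gap=25.0)
        assert np.all(np.isnan(out[51:90]))       # inside the 40-m gap
        assert out[50] == 1.0 and out[90] == 1.0  # samples themselves survive
        assert np.all(np.isfinite(out[:51]))

    def test_no_extrapolation(self):
        out = pp.regrid_profile([10.0, 20.0], [1.0, 1.0], np.arange(0.0, 31.0))
        assert np.all(np.isnan(out[:10])) and np.all(np.isnan(out[21:]))

    def test_too_few_samples_unusable(self):
        out = pp.regrid_profile([10.0], [1.0], np.arange(0.0, 20.0))
        assert np.all(np.isnan(out))


class TestMldBio:
    def test_sharp_ramp_detected_at_centre(self):
        z = np.arange(0.0, 200.0)
        chl = np.where(z <= 50, 1.0, np.where(z >= 52, 0.1, 1.0 - 0.45 * (z - 50)))
        assert pp.mld_bio(z, chl) == pytest.approx(51.0, abs=0.5)

    def test_uniform_profile_undefined(self):
        z = np.arange(0.0, 200.0)
        assert np.isnan(pp.mld_bio(z, np.full(z.shape, 0.7)))

    def test_tied_maxima_break_shallow(self):
        z = np.arange(0.0, 300.0)
        chl = np.full(z.shape, 2.0)
        chl[z >= 60] = 1.5
        chl[z >= 120] = 1.0  # identical 0.5-step gradients at 60 and 120 m
        assert pp.mld_bio(z, chl) == pytest.approx(60.0, abs=1.0)

    def test_translation_equivariance(self):
        z = np.arange(0.0, 300.0)
        chl = np.where(z <= 80, 1.0, 0.1 + 0.9 * np.exp(-(z - 80) / 5.0))
        base = pp.mld_bio(z, chl)
        shifted = pp.mld_bio(z, np.interp(z - 40.0, z, chl))
        assert shifted == pytest.approx(base + 40.0, abs=1.0)


class TestMldDensity:
    def test_step_threshold_crossing(self):
        z = np.arange(0.0, 200.0)
        sigma = np.where(z < 80, 27.0, 27.02)
        depth, mixed = pp.mld_density(z, sigma)
        assert depth == 80.0 and not mixed

    def test_uniform_column_flagged_fully_mixed(self):
        z = np.arange(0.0, 200.0)
        depth, mixed = pp.mld_density(z, np.full(z.shape, 27.0))
        assert depth == 199.0 and mixed

    def test_gradient_from_reference_depth(self):
        z = np.arange(0.0, 100.0)
        sigma = 27.0 + np.clip(z - 5.0, 0.0, None) * 0.01
        depth, mixed = pp.mld_density(z, sigma)
        assert depth == 7.0 and not mixed  # first depth strictly past +0.01


class TestIpar:
    def test_dark_profile_zero(self):
        z = np.arange(0.0, 3.0)
        ed = np.zeros((4, 3))
        out = pp.compute_ipar(z, ed)
        np.testing.assert_allclose(out, 0.0)

    def test_flat_spectrum_matches_quanta_integral(self):
        # analytic: 0.01 W m-2 nm-1 over 400-700 nm = 13.79 umol m-2 s-1
        z = np.zeros(1)
        ed = np.full((4, 1), 0.01)
        out = pp.compute_ipar(z, ed)
        assert out[0] == pytest.approx(13.79, rel=0.05)

    def test_linear_in_irradiance(self):
        z = np.zeros(2)
        ed = np.column_stack((np.array([0.5, 0.6, 0.55, 0.4]),
                              np.array([0.5, 0.6, 0.55, 0.4]) * np.exp(-1.0)))
        out = pp.compute_ipar(z, ed)
        assert out[1] / out[0] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_too_few_channels_masked(self):
        z = np.zeros(1)
        ed = np.array([[0.1], [np.nan], [np.nan], [0.1]])
        assert np.isnan(pp.compute_ipar(z, ed)[0])


class TestNpqCorrection:
    def _setup(self):
        z = np.arange(0.0, 100.0)
        chl = np.where(z <= 20, 0.4 + 0.03 * z, 1.0)
        chl[z > 45] = 0.2
        ipar = 15.0 * np.exp((35.0 - z) * 0.1)  # isolume exactly at 35 m
        return z, chl, ipar

    def test_night_profile_unchanged(self):
        z, chl, ipar = self._setup()
        out, depth = pp.correct_npq(z, chl, ipar, 45.0, sun_elevation=0.0)
        np.testing.assert_array_equal(out, chl)
        assert np.isnan(depth)

    def test_daytime_quenched_surface_restored(self):
        z, chl, ipar = self._setup()
        out, depth = pp.correct_npq(z, chl, ipar, 45.0, sun_elevation=30.0)
        assert depth == 20.0
        np.testing.assert_allclose(out[z < 20], 1.0)
        np.testing.assert_array_equal(out[z >= 20], chl[z >= 20])

    def test_max_below_isolume_leaves_profile(self):
        z = np.arange(0.0, 100.0)
        chl = np.where(z <= 40, 0.5, 0.2)
        chl[40] = 1.0  # maximum at 40 m
        ipar = 15.0 * np.exp((30.0 - z) * 0.1)  # isolume at 30 m
        out, depth = pp.correct_npq(z, chl, ipar, 50.0, sun_elevation=30.0)
        np.testing.assert_array_equal(out, chl)
        assert np.isnan(depth)

    def test_never_decreases_chl(self):
        z, chl, ipar = self._setup()
        out, _ = pp.correct_npq(z, chl, ipar, 45.0, sun_elevation=30.0)
        assert np.all(out >= chl - 1e-12)


class TestCarbonConversions:
    def test_poc_intercept_at_zero_backscatter(self):
        assert pp.carbon_from_backscatter(0.0, 700) == pytest.approx(3.04)

    def test_poc_linear_evaluation(self):
        assert pp.carbon_from_backscatter(1e-3, 700) == pytest.approx(34.24)

    def test_cphyto_linear_evaluation(self):
        assert pp.carbon_from_backscatter(1e-3, 470) == pytest.approx(12.718)

    def test_negative_backscatter_masked(self):
        assert np.isnan(pp.carbon_from_backscatter(-1e-4, 700))

    def test_affine_linearity_probe(self):
        b = np.array([1e-4, 2e-4, 3e-4])
        poc = pp.carbon_from_backscatter(b, 700)
        assert np.diff(poc, 2) == pytest.approx(0.0, abs=1e-9)


class TestAouSpice:
    def test_saturation_gives_zero(self):
        o2 = sw.o2_saturation(10.0, 35.0)
        assert pp.compute_aou(o2, 10.0, 35.0) == pytest.approx(0.0)

    def test_supersaturated_negative(self):
        o2 = sw.o2_saturation(10.0, 35.0) * 1.05
        assert pp.compute_aou(o2, 10.0, 35.0) < 0

    def test_aou_against_solubility_oracle(self):
        assert pp.compute_aou(200.0, 10.0, 35.0) == pytest.approx(274.610 - 200.0, abs=0.01)


def test_derive_profile_chain(short_mission):
    mission, truth = short_mission
    d = pp.derive_profile(mission.profiles[5])
    assert np.isfinite(d.mld_bio)
    assert abs(d.mld_bio - truth.mld[5]) < 2.0
    assert d.poc is not None and np.nanmax(d.poc) > 0
    assert d.aou is not None and np.nanmax(d.aou) > 50.0  # deep AOU built up
    assert abs(d.mld_density - truth.mld[5]) < 10.0
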