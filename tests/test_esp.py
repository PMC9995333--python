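import numpy as np
import pytest

from floatpump import esp
from floatpump.constants import Constants, Uncertain

CONST = Constants()
Z5 = np.arange(0.0, 500.1, 5.0)
T = np.datetime64("2016-12-01T00:00:00")


def _smooth_fields(mld=100.0):
    aou = 120.0 * (1 - np.exp(-np.clip(Z5 - mld, 0, None) / 150.0))
    spice = -0.2 - 0.001 * Z5
    poc = 40.0 * np.exp(-Z5 / 150.0) + 15.0
    return aou, spice, poc


def _inject(arr, z_lo, z_hi, delta):
    out = arr.copy()
    out[(Z5 >= z_lo) & (Z5 <= z_hi)] += delta
    return out


class TestAnomalies:
    def test_smooth_profiles_near_zero(self):
        aou, spice, poc = _smooth_fields()
        an = esp.profile_anomalies(Z5, aou, spice, poc, 100.0, CONST)
        sel = (Z5 > 160) & (Z5 < 450)  # away from edges
        assert np.nanmax(np.abs(an["aou"][sel])) < 1.0
        assert np.nanmax(np.abs(an["spice"][sel])) < 0.01

    def test_inserted_layer_recovers_amplitude(self):
        # gentle background: the 30-m layer passes the median untouched and
        # the anomaly minimum reproduces the inserted depression
        aou = 100.0 + 0.02 * Z5
        _, spice, poc = _smooth_fields()
        aou = _inject(aou, 285, 315, -10.0)
        an = esp.profile_anomalies(Z5, aou, spice, poc, 100.0, CONST)
        i = np.nanargmin(an["aou"])
        assert 285 <= Z5[i] <= 315
        assert an["aou"][i] == pytest.approx(-10.0, abs=1.5)

    def test_steep_background_attenuates_anomaly(self):
        # against a steep mesopelagic AOU rise, the running-median background
        # absorbs part of the layer: the measured anomaly shrinks
        aou, spice, poc = _smooth_fields()
        aou = _inject(aou, 285, 315, -10.0)
        an = esp.profile_anomalies(Z5, aou, spice, poc, 100.0, CONST)
        assert -10.0 < np.nanmin(an["aou"]) < -3.0

    def test_search_excluded_above_mld(self):
        aou, spice, poc = _smooth_fields()
        an = esp.profile_anomalies(Z5, aou, spice, poc, 150.0, CONST)
        assert np.all(np.isnan(an["aou"][Z5 <= 150.0]))

    def test_too_few_bins_skips_profile(self):
        aou, spice, poc = _smooth_fields()
        assert esp.profile_anomalies(Z5, aou, spice, poc, 450.0, CONST) is None


def _threshold_anomalies(aou_val=-6.0, spice_val=-0.06, poc_val=5.0,
                         z_lo=280, z_hi=320):
    zero = np.zeros(Z5.shape)
    an = {"aou": _inject(zero, z_lo, z_hi, aou_val),
          "spice": _inject(zero.copy(), z_lo, z_hi, spice_val),
          "poc": _inject(zero.copy(), z_lo, z_hi, poc_val)}
    for k in an:
        an[k][Z5 <= 100.0] = np.nan
    return an


class TestDetect:
    def test_supra_threshold_layer_detected_with_extent(self):
        an = _threshold_anomalies()
        feat = esp.detect_esp_feature(T, Z5, an, np.full(Z5.shape, 30.0), CONST)
        assert feat is not None
        assert (feat.top, feat.bottom) == (280.0, 320.0)
        assert feat.z_ev == pytest.approx(300.0)
        assert feat.poc_ev == pytest.approx(30.0)

    def test_sub_threshold_aou_not_detected(self):
        an = _threshold_anomalies(aou_val=-4.0)
        assert esp.detect_esp_feature(T, Z5, an, np.zeros(Z5.shape), CONST) is None

    def test_shallowest_candidate_wins(self):
        an = _threshold_anomalies(z_lo=140, z_hi=160)
        deep = _threshold_anomalies(z_lo=310, z_hi=330)
        for k in an:
            merged = np.where(np.isfinite(deep[k]) & (deep[k] != 0), deep[k], an[k])
            an[k] = merged
        feat = esp.detect_esp_feature(T, Z5, an, np.zeros(Z5.shape), CONST)
        assert feat.z_ev == pytest.approx(150.0)

    def test_extent_spans_both_negative_runs(self):
        an = _threshold_anomalies()
        # widen only the spice negative run: bottom should follow the deeper
        an["spice"] = _inject(an["spice"], 325, 340, -0.02)
        feat = esp.detect_esp_feature(T, Z5, an, np.zeros(Z5.shape), CONST)
        assert feat.bottom == 340.0


class TestFlux:
    def _feature(self, poc_surf=100.0, sd=0.0):
        f = esp.EspFeature(time=T, z_ev=400.0, poc_ev=80.0, aou_anom=-6,
                           spice_anom=-0.06, poc_anom=5.0, top=380.0, bottom=420.0)
        f.poc_surf = Uncertain(poc_surf, sd)
        f.mld = Uncertain(100.0, 0.0)
        return f

    def test_worked_deterministic_flux(self):
        const = Constants(respiration=Uncertain(0.33, 0.0))
        s = esp.esp_flux(self._feature(), const, n_iter=100)
        assert s.median == pytest.approx(495.0, rel=1e-9)

    def test_clock_undefined_when_parcel_richer(self):
        with pytest.raises(ValueError):
            esp.esp_flux(self._feature(poc_surf=80.0), CONST, n_iter=100)

    def test_flux_proportional_to_respiration(self):
        s1 = esp.esp_flux(self._feature(),
                          Constants(respiration=Uncertain(0.33, 0.0)), n_iter=100)
        s2 = esp.esp_flux(self._feature(),
                          Constants(respiration=Uncertain(0.66, 0.0)), n_iter=100)
        assert s2.median == pytest.approx(2 * s1.median, rel=1e-9)

    def test_gross_export_never_negative(self):
        s = esp.esp_flux(self._feature(poc_surf=85.0, sd=30.0), CONST,
                         seed=2, n_iter=4000)
        assert s.n_rejected > 0
        assert s.q25 > 0  # rejected draws cannot drag the summary negative


class TestMissionDetection:
    def test_every_injected_feature_detected(self, full_mission, constants):
        from floatpump.preprocess import derive_profile
        mission, truth = full_mission
        hits = 0
        for pid, z_ev in zip(truth.esp["profile_id"], truth.esp["z_ev"]):
            d = derive_profile(mission.profiles[pid], constants, with_light=False)
            an, feat = _detect_on(d, constants)
            assert feat is not None
            assert abs(feat.z_ev - z_ev) < 25.0
            hits += 1
        assert hits == len(truth.esp)

    def test_no_detection_in_event_free_mission(self, constants):
        import dataclasses
        from floatpump.preprocess import derive_profile
        from floatpump.synthetic import MissionConfig, generate_mission
        cfg = dataclasses.replace(MissionConfig(), duration_days=60.0, esp_events=())
        mission, _ = generate_mission(cfg, seed=23)
        for p in mission.profiles:
            d = derive_profile(p, constants, with_light=False)
            _, feat = _detect_on(d, constants)
            assert feat is None


def _detect_on(d, const):
    z5 = np.arange(0.0, const.esp_zmax + 1e-9, const.esp_grid)

    def to5(v):
        ok = np.isfinite(v)
        return np.interp(z5, d.z[ok], v[ok], left=np.nan, right=np.nan)

    an = esp.profile_anomalies(z5, to5(d.aou), to5(d.spice), to5(d.poc),
                               d.mld_bio, const)
    if an is None:
        return None, None
    return an, esp.detect_esp_feature(d.time, z5, an, to5(d.poc), const)
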