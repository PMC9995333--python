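import numpy as np
import pandas as pd
import pytest

from floatpump import spikes
from floatpump.constants import Constants, Uncertain

CONST = Constants()


def _flat_profile(depth=500, blank=0.1):
    z = np.arange(0.0, float(depth))
    return z, np.full(z.shape, blank)


class TestDecompose:
    def test_smooth_profile_has_no_spikes(self):
        z = np.arange(0.0, 500.0)
        signal = 0.3 + 0.5 * np.exp(-z / 80.0)  # smooth, monotone
        comp = spikes.decompose_optical(z, signal)
        np.testing.assert_allclose(comp.large, 0.0, atol=1e-12)

    def test_single_spike_isolated_exactly(self):
        z, signal = _flat_profile()
        signal[250] += 0.7
        comp = spikes.decompose_optical(z, signal)
        assert comp.large[250] == pytest.approx(0.7)
        assert np.sum(comp.large > 0) == 1
        np.testing.assert_allclose(comp.baseline, 0.1)

    def test_exact_reconstruction(self):
        z, signal = _flat_profile()
        rng = np.random.default_rng(0)
        for k in rng.integers(20, 480, size=8):
            signal[k] += rng.uniform(0.1, 1.0)
        comp = spikes.decompose_optical(z, signal)
        np.testing.assert_allclose(comp.reconstruction(), signal, atol=1e-12)

    def test_blank_from_deep_baseline(self):
        z = np.arange(0.0, 500.0)
        signal = np.where(z < 450, 0.5, 0.2)
        comp = spikes.decompose_optical(z, signal)
        assert comp.blank == pytest.approx(0.2)
        assert not comp.blank_from_default

    def test_shallow_profile_falls_back_to_default_blank(self):
        z = np.arange(0.0, 150.0)
        comp = spikes.decompose_optical(z, np.full(z.shape, 0.5), default_blank=0.05)
        assert comp.blank == 0.05 and comp.blank_from_default

    def test_idempotent_on_baseline(self):
        z, signal = _flat_profile()
        signal[100] += 1.0
        comp = spikes.decompose_optical(z, signal)
        again = spikes.decompose_optical(z, comp.baseline)
        np.testing.assert_allclose(again.large, 0.0, atol=1e-12)


def _bin_means(mean, sd=0.0, n=5):
    return pd.DataFrame([{"bin_start": 0.0, "bin_end": 10.0, "mean": mean,
                          "sd": sd, "n_obs": n}])


class TestSpikeFlux:
    def test_deterministic_poc_product(self):
        const = Constants(w_bbl=Uncertain(74.0, 0.0),
                          q_bbp_poc=Uncertain(3.12e4, 0.0))
        out = spikes.spike_flux(_bin_means(1e-4), "poc", const, seed=0, n_iter=200)
        assert out.loc[0, "median"] == pytest.approx(230.88)
        assert out.loc[0, "q75"] - out.loc[0, "q25"] == pytest.approx(0.0)

    def test_zero_concentration_zero_flux_no_intercept(self):
        out = spikes.spike_flux(_bin_means(0.0), "poc", CONST, seed=0, n_iter=500)
        assert out.loc[0, "median"] == pytest.approx(0.0, abs=1e-9)

    def test_mc_median_within_3_se(self):
        out = spikes.spike_flux(_bin_means(1e-4), "poc", CONST, seed=0, n_iter=5000)
        # first-order sd of the product / sqrt(n)
        sd = 230.88 * np.sqrt((45 / 74) ** 2 + (2.47e3 / 3.12e4) ** 2)
        assert abs(out.loc[0, "median"] - 230.88) < 3 * sd / np.sqrt(5000) + 1.5

    def test_chl_flux_scales_linearly(self):
        const = Constants(w_chl=Uncertain(98.0, 0.0))
        f1 = spikes.spike_flux(_bin_means(0.2), "chl", const, n_iter=100)
        f3 = spikes.spike_flux(_bin_means(0.6), "chl", const, n_iter=100)
        assert f3.loc[0, "median"] == pytest.approx(3 * f1.loc[0, "median"])

    def test_empty_bin_propagates_n_zero(self):
        means = pd.DataFrame([{"bin_start": 0.0, "bin_end": 10.0, "mean": np.nan,
                               "sd": np.nan, "n_obs": 0}])
        out = spikes.spike_flux(means, "poc", CONST, n_iter=100)
        assert out.loc[0, "n_obs"] == 0 and np.isnan(out.loc[0, "median"])


def test_stratum_means_pool_below_mixing_layer():
    z = np.arange(0.0, 500.0)
    large = np.zeros(z.shape)
    large[(z > 100) & (z <= 200)] = 2e-4  # exactly the stratum
    large[z <= 100] = 9.9                 # must be excluded
    t = np.array(["2020-01-01", "2020-01-05"], dtype="datetime64[s]")
    out = spikes.stratum_bin_means(t, [z, z], [large, large], [100.0, 100.0])
    assert out.loc[0, "mean"] == pytest.approx(2e-4)


def test_mission_spike_flux_recovers_injection(full_mission, constants):
    """10-d mean spike concentrations recover the generator's injections."""
    from floatpump.preprocess import derive_profile
    mission, truth = full_mission
    idx = range(0, 60)  # bloom-season profiles
    comps, mlds, ts, zs = [], [], [], []
    for i in idx:
        p = mission.profiles[i]
        d = derive_profile(p, constants, with_light=False)
        comps.append(spikes.decompose_optical(d.z, p.bbp700,
                                              constants.default_bbp_blank, constants))
        mlds.append(d.mld_bio)
        ts.append(p.time)
        zs.append(d.z)
    means = spikes.stratum_bin_means(np.array(ts), zs, [c.large for c in comps], mlds)
    # truth: injected amplitudes in (mld, mld+100] averaged over the stratum
    sp = truth.spikes
    est, true = [], []
    for _, b in means.iterrows():
        if b["n_obs"] == 0:
            continue
        tot = 0.0
        nprof = 0
        for i in idx:
            if not (b["bin_start"] <= np.datetime64(mission.profiles[i].time) < b["bin_end"]):
                continue
            nprof += 1
            mine = sp[(sp["profile_id"] == i) & (sp["z"] > mlds[i])
                      & (sp["z"] <= mlds[i] + 100.0)]
            tot += mine["bbp_amp"].sum()
        if nprof:
            est.append(b["mean"])
            true.append(tot / (nprof * 100.0))
    est, true = np.array(est), np.array(true)
    assert np.sum(true) > 0
    assert np.sum(est) == pytest.approx(np.sum(true), rel=0.25)
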