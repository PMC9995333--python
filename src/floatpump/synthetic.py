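"""Synthetic float missions with known ground truth.

Generates complete missions -- profile time series plus parking-depth
attenuance records -- that emulate the statistical structure the analysis
assumes: a seasonal mixing-layer cycle with sub-seasonal AR(1) variability,
a bloom in small-particle chlorophyll and backscattering homogeneous over
the mixing layer, large-particle spikes below it, injectable subsurface
anomaly layers (negative AOU and spice, positive POC), parking attenuance
with a continuous slope plus discrete jumps, exponentially attenuated
irradiance with chlorophyll-coupled attenuation, and a known quenching law
on daytime profiles.  Every injected quantity is recorded exactly once in
:class:`SyntheticTruth`, the only source estimator recovery tests may read.

The generator is deliberately not hydrodynamic: fields are closed-form
functions of depth, time and the mixing-layer depth, so ground-truth stocks
and fluxes are computable by quadrature independently of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import seawater
from .core import ParkingSeries, Profile
from .size import BBP_PRESET, CP_PRESET, alpha_tau

__all__ = [
    "MLDConfig", "BloomConfig", "SpikeConfig", "EspEvent", "TrapConfig",
    "SizeConfig", "MissionConfig", "Mission", "SyntheticTruth",
    "generate_mission",
]

_HC_NA = 6.62607015e-34 * 2.99792458e8 * 6.02214076e23


@dataclass(frozen=True)
class MLDConfig:
    winter_max: float = 300.0     # m
    summer_min: float = 50.0      # m
    winter_peak_day: float = -30.0  # relative to mission start
    period_days: float = 365.0
    ar1_sd: float = 12.0          # m, sub-seasonal excursions
    ar1_phi: float = 0.7


@dataclass(frozen=True)
class BloomConfig:
    base_chl: float = 0.45        # mg m-3, pre-bloom mixed-layer chlorophyll
    decline_efold_days: float = 400.0
    peak_chl: float = 1.5         # bloom amplitude on top of the base
    apex_day: float = 100.0
    width_days: float = 30.0
    bbp_per_chl: float = 1.8e-3   # m-1 per mg chl m-3
    bbp_offset: float = 2.0e-4    # m-1, non-algal mixed-layer background
    chl_deep: float = 0.02        # mg m-3
    bbp_deep: float = 4.5e-4      # m-1 (deep blank + refractory)
    ramp_half_width: float = 2.0  # m, sharp transition at the mixing layer
    ramp_fraction: float = 0.25   # value at the ramp bottom / mixed value
    chl_decay_scale: float = 40.0  # m, sub-ramp e-folding
    bbp_decay_scale: float = 60.0


@dataclass(frozen=True)
class SpikeConfig:
    rate_per_profile: float = 6.0     # mean spikes per profile below the ML
    chl_amp_median: float = 0.25      # mg m-3
    bbp_amp_median: float = 8.0e-4    # m-1
    lognorm_sd: float = 0.6
    depth_efold: float = 250.0        # m, amplitude attenuation below the ML
    bloom_coupled: bool = True        # rate scales with bloom intensity


@dataclass(frozen=True)
class EspEvent:
    """An injected subducted parcel.

    ``d_aou``/``d_spice``/``d_poc`` are in-situ contrasts between the parcel
    and the ambient water.  A subducted surface parcel carries near-zero AOU
    into a mesopelagic background of ~100 umol kg-1, so the default AOU
    contrast is large; the *measured* anomaly against a 100-m running-median
    background is roughly half the contrast when the background gradient is
    steep.
    """

    day: float
    z_ev: float
    thickness: float = 30.0
    d_aou: float = -25.0     # umol kg-1
    d_spice: float = -0.10
    d_poc: float = 20.0      # mg C m-3


@dataclass(frozen=True)
class TrapConfig:
    base_slope: float = 1.0e-4        # m2 m-2 h-1 pre-bloom accumulation
    bloom_coupled: bool = True
    jump_rate_per_day: float = 0.5
    jump_median: float = 3.0e-3       # m2 m-2
    jump_lognorm_sd: float = 0.5
    noise_sd: float = 1.0e-4          # Gaussian on ATN
    optical_spike_rate_per_day: float = 0.3
    optical_spike_amp: float = 4.0e-3
    settle_offset: float = 5.0e-3     # transient on the first samples
    atn0: float = 0.05


@dataclass(frozen=True)
class SizeConfig:
    d_base_um: float = 120.0
    d_peak_um: float = 130.0          # added at the bloom apex
    cp_base: float = 0.05             # m-1 mixed-layer beam attenuation
    cp_per_chl: float = 0.25          # m-1 per mg chl m-3
    cp_deep: float = 0.02


@dataclass(frozen=True)
class MissionConfig:
    start: str = "2016-09-24"
    duration_days: float = 365.0
    cadence_days: float = 2.0
    z_max: float = 500.0
    dz: float = 1.0
    lat: float = -55.0
    lon: float = -120.0
    parking_depth: float = 300.0
    mld: MLDConfig = MLDConfig()
    bloom: BloomConfig = BloomConfig()
    spikes: SpikeConfig = SpikeConfig()
    # default catalog: events while the surface is POC-rich, so the
    # subducted parcels are leaner than the contemporaneous mixed layer
    # (the respiration clock requires POC_surf > POC_ev)
    esp_events: tuple = (
        EspEvent(day=40.0, z_ev=380.0),
        EspEvent(day=110.0, z_ev=400.0),
        EspEvent(day=150.0, z_ev=300.0),
    )
    trap: TrapConfig = TrapConfig()
    size: SizeConfig = SizeConfig()
    alpha_npq: float = 5.0e-3       # per umol photons m-2 s-1, quench law
    t_surf_mean: float = 4.0
    t_surf_amp: float = 2.0
    t_deep: float = 1.5
    s_surf: float = 34.0
    s_deep: float = 34.4
    ts_decay_scale: float = 30.0    # m, thermocline/halocline e-folding
    aou_max: float = 120.0          # umol kg-1 approached at depth
    aou_scale: float = 150.0
    chl_noise_sd: float = 0.004
    ts_noise_sd: float = 0.002
    bbp_deep_noise_sd: float = 3.0e-6
    ed0: tuple = (0.7, 0.8, 0.75, 0.55)   # W m-2 nm-1 noon surface channels
    ed_wavelengths: tuple = (412.0, 443.0, 490.0, 550.0)
    mld_bio_offset: float = 0.0     # decouple MLD_bio from density MLD


@dataclass
class Mission:
    profiles: list
    parkings: list
    config: MissionConfig


@dataclass
class SyntheticTruth:
    """Ground truth of one generated mission (see field comments)."""

    times: np.ndarray                # profile times
    mld: np.ndarray                  # true mixing-layer depth per profile, m
    chl_ml: np.ndarray               # mixed-layer chlorophyll path
    bbp_ml: np.ndarray
    mlp_stocks: pd.DataFrame         # per consecutive pair: analytic stock
    trap: pd.DataFrame               # per phase: slope, jumps, true fluxes
    esp: pd.DataFrame                # injected feature catalog
    spikes: pd.DataFrame             # injected optical spikes (per profile)
    diameter_um: np.ndarray          # true mean particle diameter path
    alpha_npq: float
    phenology: dict                  # onset/climax/apex datetimes
    p_dense: pd.DataFrame            # dense noise-free phytoplankton stock


# ---------------------------------------------------------------------------
# closed-form fields


class _Fields:
    """Closed-form mission fields; shared by data generation and truth."""

    def __init__(self, cfg: MissionConfig):
        self.cfg = cfg

    def mld_deterministic(self, day):
        m = self.cfg.mld
        phase = 2 * np.pi * (np.asarray(day, float) - m.winter_peak_day) / m.period_days
        return m.summer_min + 0.5 * (m.winter_max - m.summer_min) * (1 + np.cos(phase))

    def chl_ml(self, day):
        b = self.cfg.bloom
        day = np.asarray(day, float)
        return b.base_chl * np.exp(-day / b.decline_efold_days) + b.peak_chl * np.exp(
            -0.5 * ((day - b.apex_day) / b.width_days) ** 2
        )

    def bloom_factor(self, day):
        return self.chl_ml(day) / self.cfg.bloom.base_chl

    def bbp_ml(self, day):
        b = self.cfg.bloom
        return b.bbp_per_chl * self.chl_ml(day) + b.bbp_offset

    def _shape(self, z, mld, decay_scale):
        """1 in the mixed layer, sharp ramp at the base, exponential tail."""
        b = self.cfg.bloom
        z = np.asarray(z, float)
        h = b.ramp_half_width
        ramp = 1.0 - (1.0 - b.ramp_fraction) * (z - (mld - h)) / (2 * h)
        tail = b.ramp_fraction * np.exp(-(z - (mld + h)) / decay_scale)
        return np.where(z <= mld - h, 1.0, np.where(z < mld + h, ramp, tail))

    def chl(self, z, day, mld):
        b = self.cfg.bloom
        return b.chl_deep + (self.chl_ml(day) - b.chl_deep) * self._shape(z, mld, b.chl_decay_scale)

    def bbp700(self, z, day, mld):
        b = self.cfg.bloom
        return b.bbp_deep + (self.bbp_ml(day) - b.bbp_deep) * self._shape(z, mld, b.bbp_decay_scale)

    def bbp470(self, z, day, mld):
        return 1.45 * self.bbp700(z, day, mld)

    def t_surf(self, day):
        c = self.cfg
        return c.t_surf_mean - c.t_surf_amp * np.cos(2 * np.pi * (np.asarray(day, float) - 120.0) / 365.0)

    def temperature(self, z, day, mld):
        c = self.cfg
        shape = np.where(
            np.asarray(z, float) <= mld, 1.0,
            np.exp(-(np.asarray(z, float) - mld) / c.ts_decay_scale),
        )
        return c.t_deep + (self.t_surf(day) - c.t_deep) * shape

    def salinity(self, z, day, mld):
        c = self.cfg
        shape = np.where(
            np.asarray(z, float) <= mld, 1.0,
            np.exp(-(np.asarray(z, float) - mld) / c.ts_decay_scale),
        )
        return c.s_deep + (c.s_surf - c.s_deep) * shape

    def aou(self, z, mld):
        c = self.cfg
        z = np.asarray(z, float)
        return np.where(z <= mld, 0.0, c.aou_max * (1 - np.exp(-(z - mld) / c.aou_scale)))

    def kd(self, day):
        """Per-channel diffuse attenuation, chlorophyll coupled (m-1)."""
        chl = self.chl_ml(day)
        kw = np.array([0.008, 0.0065, 0.0166, 0.0638])
        chi = np.array([0.126, 0.0995, 0.0773, 0.0452])
        return kw + chi * chl**0.67

    def kd_par(self, day):
        kd490 = self.kd(day)[2]
        return 0.0665 + 0.874 * kd490 - 0.00121 / kd490

    def surface_ed(self, elev_deg):
        daylight = max(np.sin(np.deg2rad(elev_deg)), 0.0)
        return np.asarray(self.cfg.ed0, float) * daylight * 2.0

    def ipar0(self, ed_surface):
        """Surface iPAR from the four channels by piecewise-linear quanta
        integration (independent of the pipeline's spline estimator)."""
        wl = np.asarray(self.cfg.ed_wavelengths, float)
        lam = np.arange(400.0, 701.0)
        spec = np.interp(lam, wl, ed_surface)
        q = spec * lam * 1e-9 / _HC_NA * 1e6
        return float(np.trapezoid(q, lam))

    def ipar(self, z, day, ipar0):
        return ipar0 * np.exp(-self.kd_par(day) * np.asarray(z, float))

    def diameter_um(self, day):
        s = self.cfg.size
        b = self.cfg.bloom
        bloom = np.exp(-0.5 * ((np.asarray(day, float) - b.apex_day) / b.width_days) ** 2)
        return s.d_base_um + s.d_peak_um * bloom

    def cp_ml(self, day):
        s = self.cfg.size
        return s.cp_base + s.cp_per_chl * self.chl_ml(day)


def _density_compensated_perturbation(T0, S0, d_spice):
    """(dT, dS) giving the requested spice change at ~zero density change."""
    eps = 1e-3
    drho_dT = (seawater.density_anomaly(T0 + eps, S0) - seawater.density_anomaly(T0 - eps, S0)) / (2 * eps)
    drho_dS = (seawater.density_anomaly(T0, S0 + eps) - seawater.density_anomaly(T0, S0 - eps)) / (2 * eps)
    dpi_dT = (seawater.spiciness(T0 + eps, S0) - seawater.spiciness(T0 - eps, S0)) / (2 * eps)
    dpi_dS = (seawater.spiciness(T0, S0 + eps) - seawater.spiciness(T0, S0 - eps)) / (2 * eps)
    A = np.array([[drho_dT, drho_dS], [dpi_dT, dpi_dS]])
    dT, dS = np.linalg.solve(A, np.array([0.0, d_spice]))
    return float(dT), float(dS)


# ---------------------------------------------------------------------------
# generation


def _profile_times(cfg: MissionConfig):
    """Profile times alternating local noon / local midnight."""
    start = np.datetime64(cfg.start, "s")
    noon_utc_h = (12.0 - cfg.lon / 15.0) % 24.0
    times = []
    days = np.arange(0.0, cfg.duration_days + 1e-9, cfg.cadence_days)
    for i, d in enumerate(days):
        hour = noon_utc_h if i % 2 == 0 else (noon_utc_h + 12.0) % 24.0
        times.append(start + np.timedelta64(int((d * 24 + hour) * 3600), "s"))
    return days, np.array(times, dtype="datetime64[s]")


def generate_mission(config: MissionConfig = MissionConfig(), seed: int = 0):
    """Generate a mission and its ground truth.  Bit-identical per seed."""
    cfg = config
    f = _Fields(cfg)
    rng = np.random.default_rng(seed)

    # validate the ESP catalog before doing any work
    for ev in cfg.esp_events:
        mld_at = f.mld_deterministic(ev.day)
        if ev.z_ev - ev.thickness / 2 <= mld_at:
            raise ValueError(
                f"ESP event at day {ev.day} (z_ev={ev.z_ev} m) overlaps the "
                f"mixing layer ({mld_at:.0f} m)"
            )
        if ev.z_ev + ev.thickness / 2 > cfg.z_max:
            raise ValueError("ESP event deeper than the sampled column")

    days, times = _profile_times(cfg)
    n = days.size
    z = np.arange(0.0, cfg.z_max + 1e-9, cfg.dz)

    # true mixing-layer path: seasonal cycle + AR(1) excursions
    m = cfg.mld
    noise = np.zeros(n)
    innov = rng.normal(0.0, m.ar1_sd * np.sqrt(max(1 - m.ar1_phi**2, 1e-12)), size=n)
    for i in range(1, n):
        noise[i] = m.ar1_phi * noise[i - 1] + innov[i]
    if m.ar1_sd == 0:
        noise[:] = 0.0
    mld_true = np.clip(f.mld_deterministic(days) + noise, m.summer_min * 0.5, cfg.z_max - 100.0)

    # which profile carries which ESP event
    esp_rows = []
    esp_by_profile: dict[int, list[EspEvent]] = {}
    for ev in cfg.esp_events:
        i = int(np.argmin(np.abs(days - ev.day)))
        esp_by_profile.setdefault(i, []).append(ev)

    profiles = []
    spike_rows = []
    alpha = cfg.alpha_npq
    par_sat_path = 21.5 - 13.5 * np.cos(2 * np.pi * (days - 120.0) / 365.0)

    for i in range(n):
        day, t, mld = days[i], times[i], float(mld_true[i])
        mld_bio_true = mld + cfg.mld_bio_offset
        chl = f.chl(z, day, mld_bio_true)
        bbp700 = f.bbp700(z, day, mld_bio_true)
        T = f.temperature(z, day, mld)
        S = f.salinity(z, day, mld)
        aou = f.aou(z, mld)

        # optical size noise in the upper 50 m with the variance implied by
        # the true particle diameter (residence-time correction included)
        d_m = f.diameter_um(day) * 1e-6
        a0 = np.pi * (d_m / 2.0) ** 2
        upper = z <= 50.0
        cp = np.where(z <= mld, f.cp_ml(day),
                      cfg.size.cp_deep
                      + (f.cp_ml(day) - cfg.size.cp_deep) * np.exp(-(z - mld) / 50.0))
        var_cp = alpha_tau(CP_PRESET.tau) * (CP_PRESET.Q * a0 / CP_PRESET.V) * f.cp_ml(day)
        cp = cp + np.where(upper, rng.normal(0.0, np.sqrt(var_cp), z.size), 0.0)

        bbp470 = f.bbp470(z, day, mld_bio_true)
        for arr in (bbp700, bbp470):
            mu = np.abs(arr)
            var_bb = alpha_tau(BBP_PRESET.tau) * (BBP_PRESET.Q * a0 / BBP_PRESET.V) * mu
            arr += np.where(upper, rng.normal(0.0, 1.0, z.size) * np.sqrt(var_bb),
                            rng.normal(0.0, cfg.bbp_deep_noise_sd, z.size))

        # large-particle spikes below the mixing layer
        sp = cfg.spikes
        rate = sp.rate_per_profile * (f.bloom_factor(day) if sp.bloom_coupled else 1.0)
        n_spikes = rng.poisson(rate)
        for _ in range(n_spikes):
            zs = rng.uniform(mld_bio_true + 5.0, cfg.z_max - 5.0)
            atten = np.exp(-(zs - mld_bio_true) / sp.depth_efold)
            a_chl = rng.lognormal(np.log(sp.chl_amp_median), sp.lognorm_sd) * atten
            a_bbp = rng.lognormal(np.log(sp.bbp_amp_median), sp.lognorm_sd) * atten
            k = int(round(zs / cfg.dz))
            chl[k] += a_chl
            bbp700[k] += a_bbp
            bbp470[k] += 1.45 * a_bbp
            spike_rows.append({"profile_id": i, "time": t, "z": z[k],
                               "chl_amp": a_chl, "bbp_amp": a_bbp})

        # subsurface anomaly (eddy subduction) layers
        for ev in esp_by_profile.get(i, ()):
            layer = np.abs(z - ev.z_ev) <= ev.thickness / 2.0
            T0 = float(np.mean(T[layer]))
            S0 = float(np.mean(S[layer]))
            dT, dS = _density_compensated_perturbation(T0, S0, ev.d_spice)
            T[layer] += dT
            S[layer] += dS
            # o2 is assembled from AOU below, so the saturation shift from
            # the T/S perturbation cancels and the AOU anomaly is exact
            aou[layer] += ev.d_aou
            bbp700[layer] += ev.d_poc / 3.12e4  # published bbp700->POC slope
            bbp470[layer] += 1.45 * ev.d_poc / 3.12e4
            esp_rows.append({
                "profile_id": i, "time": t, "day": day, "z_ev": ev.z_ev,
                "thickness": ev.thickness, "d_aou": ev.d_aou,
                "d_spice": ev.d_spice, "d_poc": ev.d_poc,
                "mld": mld_bio_true,
            })

        o2 = seawater.o2_saturation(T, S) - aou
        T = T + rng.normal(0.0, cfg.ts_noise_sd, z.size)
        S = S + rng.normal(0.0, cfg.ts_noise_sd / 4.0, z.size)

        # irradiance and the quenching law
        elev = float(seawater.solar_elevation(t, cfg.lat, cfg.lon))
        ed_surf = f.surface_ed(elev)
        kd = f.kd(day)
        ed = ed_surf[:, None] * np.exp(-kd[:, None] * z[None, :])
        if elev > 0:
            ipar0 = f.ipar0(ed_surf)
            chl_meas = chl / (1.0 + alpha * f.ipar(z, day, ipar0))
        else:
            chl_meas = chl.copy()
        chl_meas = chl_meas + rng.normal(0.0, cfg.chl_noise_sd, z.size)

        profiles.append(Profile(
            time=t, lat=cfg.lat, lon=cfg.lon, z=z.copy(),
            T=T, S=S, sigma=None, chl=chl_meas,
            bbp470=bbp470, bbp700=bbp700, cp660=cp, o2=o2,
            ed=ed, ed_wavelengths=cfg.ed_wavelengths,
            par_sat=float(par_sat_path[i]), profile_id=i,
        ))

    # ---- parking records -------------------------------------------------
    parkings, trap_rows = [], []
    tr = cfg.trap
    for i in range(n - 1):
        p_start = times[i] + np.timedelta64(2 * 3600, "s")
        p_end = times[i + 1] - np.timedelta64(2 * 3600, "s")
        dur_h = (p_end - p_start) / np.timedelta64(1, "h")
        if dur_h < 6:
            continue
        th = np.arange(0.0, np.floor(dur_h) + 0.5, 1.0)
        mid_day = 0.5 * (days[i] + days[i + 1])
        slope = tr.base_slope * (f.bloom_factor(mid_day) if tr.bloom_coupled else 1.0)
        atn = tr.atn0 + slope * th
        dur_d = float(th[-1]) / 24.0
        n_jumps = rng.poisson(tr.jump_rate_per_day * dur_d)
        jump_sum = 0.0
        for _ in range(n_jumps):
            jt = rng.uniform(4.0, float(th[-1]) - 1.0)
            jmag = rng.lognormal(np.log(tr.jump_median), tr.jump_lognorm_sd)
            atn = atn + np.where(th >= jt, jmag, 0.0)
            jump_sum += jmag
        n_opt = rng.poisson(tr.optical_spike_rate_per_day * dur_d)
        for _ in range(n_opt):
            k = rng.integers(4, th.size - 4)
            atn[k] += tr.optical_spike_amp
        atn[: 3] += tr.settle_offset * np.array([1.0, 0.6, 0.3])[: min(3, atn.size)]
        atn = atn + rng.normal(0.0, tr.noise_sd, th.size)
        parkings.append(ParkingSeries(start=p_start, end=p_end, t=th, atn=atn,
                                      depth=cfg.parking_depth, phase_id=i))
        trap_rows.append({
            "phase_id": i, "start": p_start, "end": p_end,
            "duration_days": dur_d, "slope_per_h": slope,
            "jump_sum": jump_sum, "n_jumps": n_jumps,
            "continuous_true": 24.0 * slope,
            "pulsed_true": jump_sum / dur_d,
        })

    # ---- ground truth ----------------------------------------------------
    truth = SyntheticTruth(
        times=times,
        mld=mld_true + cfg.mld_bio_offset,
        chl_ml=f.chl_ml(days),
        bbp_ml=f.bbp_ml(days),
        mlp_stocks=_true_mlp_stocks(f, days, times, mld_true + cfg.mld_bio_offset),
        trap=pd.DataFrame(trap_rows),
        esp=pd.DataFrame(esp_rows),
        spikes=pd.DataFrame(spike_rows),
        diameter_um=f.diameter_um(days),
        alpha_npq=alpha,
        phenology=_true_phenology(f, cfg),
        p_dense=_dense_stock(f, cfg),
    )
    return Mission(profiles=profiles, parkings=parkings, config=cfg), truth


def simulate_counting_signal(diameter_m: float, geom, n_samples: int,
                             mean_signal: float, seed: int = 0,
                             dt: float = 0.01) -> np.ndarray:
    """First-principles optical signal of monodisperse particles.

    Particles of one diameter arrive as a Poisson process, reside ``t_res``
    seconds in the sample volume, and each measurement integrates the
    instantaneous signal over ``t_samp``.  This reproduces, from mechanism
    rather than formula, the variance-to-mean statistics that the mean-size
    estimator inverts -- including the residence-time variance reduction --
    and serves as its independent oracle.
    """
    rng = np.random.default_rng(seed)
    a0 = np.pi * (diameter_m / 2.0) ** 2
    per_particle = geom.Q * a0 / geom.V
    lam = mean_signal / per_particle          # mean particles in the volume
    rate = lam / geom.t_res                   # arrivals per second
    total_t = n_samples * geom.t_samp + geom.t_res
    n_arrivals = rng.poisson(rate * total_t)
    arrivals = np.sort(rng.uniform(0.0, total_t, n_arrivals))
    grid = np.arange(0.0, total_t, dt)
    # particles present at time t: arrived in (t - t_res, t]
    n_present = (np.searchsorted(arrivals, grid, side="right")
                 - np.searchsorted(arrivals, grid - geom.t_res, side="right"))
    inst = per_particle * n_present
    per_samp = int(round(geom.t_samp / dt))
    usable = (inst.size // per_samp) * per_samp
    return inst[:usable].reshape(-1, per_samp).mean(axis=1)[:n_samples]


def _true_mlp_stocks(f: _Fields, days, times, mld, floor: float = 100.0,
                     q: float = 3.12e4, c: float = 3.04) -> pd.DataFrame:
    """Analytic exchange stocks from the closed-form POC field (fine grid)."""
    rows = []
    zf = np.arange(0.0, f.cfg.z_max, 0.1)
    for i in range(days.size - 1):
        m0, m1 = float(mld[i]), float(mld[i + 1])
        stock = 0.0
        if m0 > m1 and m0 > floor:
            lo, hi = max(m1, floor), m0
            sgn = 1.0
        elif m1 > m0 and m1 > floor:
            lo, hi = max(m0, floor), m1
            sgn = -1.0
        else:
            lo = hi = np.nan
            sgn = 0.0
        if sgn:
            sel = (zf >= lo) & (zf <= hi)
            poc = q * f.bbp700(zf[sel], days[i], m0) + c
            stock = sgn * float(np.trapezoid(poc, zf[sel]))
        rows.append({"time_t": times[i], "time_t1": times[i + 1],
                     "mld_t": m0, "mld_t1": m1, "stock_true": stock})
    return pd.DataFrame(rows)


def _dense_stock(f: _Fields, cfg: MissionConfig, dt: float = 1.0) -> pd.DataFrame:
    """Noise-free daily phytoplankton carbon stock from the closed forms."""
    days = np.arange(0.0, cfg.duration_days + 1e-9, dt)
    zf = np.arange(0.0, cfg.z_max, 0.5)
    P = np.empty(days.size)
    for k, d in enumerate(days):
        mld = f.mld_deterministic(d) + cfg.mld_bio_offset
        chl = f.chl(zf, d, mld)
        cphy = 12.128e3 * f.bbp470(zf, d, mld) + 0.59
        valid = (chl - 0.3) > 0
        P[k] = np.trapezoid(np.where(valid, cphy, 0.0), zf)
    start = np.datetime64(cfg.start, "s")
    t = start + (days * 86400).astype("timedelta64[s]")
    return pd.DataFrame({"time": t, "day": days, "P": P})


def _true_phenology(f: _Fields, cfg: MissionConfig) -> dict:
    """Bloom milestones from the dense noise-free stock (30-d smoothing)."""
    dense = _dense_stock(f, cfg)
    P = dense["P"].to_numpy()
    days = dense["day"].to_numpy()
    k = 30  # days, matches the analysis smoothing scale
    Ps = pd.Series(P).rolling(k + 1, center=True, min_periods=1).mean().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(Ps > 0, np.gradient(Ps, days) / np.where(Ps > 0, Ps, 1.0), -np.inf)
    i_apex = int(np.argmax(Ps))
    r_pre = r[: i_apex + 1]
    i_climax = int(np.argmax(r_pre))
    crossings = [j + 1 for j in range(i_climax) if r[j] <= 0 < r[j + 1]]
    i_onset = crossings[-1] if crossings else int(np.argmax(r_pre > 0))
    t = dense["time"].to_numpy()
    return {"onset": t[i_onset], "climax": t[i_climax], "apex": t[i_apex]}
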