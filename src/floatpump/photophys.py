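"""Photophysiology: iron-stress index, mixed-layer light, bloom phenology.

Iron-stressed phytoplankton dissipate more absorbed light as heat, so the
initial slope of non-photochemical quenching (NPQ) against instantaneous
PAR, alpha_NPQ, indexes community iron stress once the ambient light effect
is removed.  The mixed-layer median light level I_ML (from satellite daily
PAR, the diffuse attenuation coefficient and the mixing-layer depth)
provides the photoacclimation context.  Bloom phenology (onset, climax,
apex) is read from the depth-integrated phytoplankton carbon stock and its
specific accumulation rate r = (1/P) dP/dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import Constants

__all__ = [
    "npq_index_profile",
    "alpha_npq_fit",
    "kd490",
    "kd_par_from_kd490",
    "mixed_layer_light",
    "phyto_stock",
    "PhenologyMetrics",
    "phenology_metrics",
]


def npq_index_profile(chl_corrected, chl_quenched):
    """NPQ(z) = (corrected - quenched) / quenched; masked where quenched <= 0."""
    corr = np.asarray(chl_corrected, dtype=float)
    quen = np.asarray(chl_quenched, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        npq = (corr - quen) / quen
    npq[~np.isfinite(quen) | (quen <= 0)] = np.nan
    return npq


def alpha_npq_fit(npq, ipar, const: Constants = Constants()):
    """Initial slope of the NPQ-iPAR curve over low light (15-75 umol m-2 s-1).

    Ordinary least squares on the pairs inside the iPAR window; returns
    ``(alpha, r2)`` or ``(None, reason)`` when fewer than 3 pairs exist or
    the fit quality is below r2 = 0.8.
    """
    npq = np.asarray(npq, dtype=float)
    ipar = np.asarray(ipar, dtype=float)
    sel = (
        np.isfinite(npq) & np.isfinite(ipar)
        & (ipar >= const.alpha_npq_ipar_min) & (ipar <= const.alpha_npq_ipar_max)
    )
    if sel.sum() < 3:
        return None, "insufficient range"
    x, y = ipar[sel], npq[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    if r2 < const.alpha_npq_r2_min:
        return None, f"r2={r2:.3f} below threshold"
    return float(slope), float(r2)


def kd490(z, ed490, zmax: float = 50.0, min_samples: int = 6):
    """Diffuse attenuation at 490 nm from a degree-4 log-irradiance fit.

    kd = minus the mean derivative of the fitted polynomial over 0-50 m,
    which for a polynomial is (p(0) - p(50)) / 50; exact for a pure
    exponential profile and invariant to scaling of the surface irradiance.
    """
    z = np.asarray(z, dtype=float)
    ed = np.asarray(ed490, dtype=float)
    sel = np.isfinite(ed) & (ed > 0) & (z <= zmax)
    if sel.sum() < min_samples:
        return np.nan
    coeffs = np.polyfit(z[sel], np.log(ed[sel]), 4)
    p = np.poly1d(coeffs)
    return float((p(0.0) - p(zmax)) / zmax)


def kd_par_from_kd490(kd: float) -> float:
    """Kd(PAR) over the upper layer from Kd(490).

    Morel et al. (2007, Remote Sens. Environ. 111), eq. 9:
    Kd(PAR) = 0.0665 + 0.874 Kd(490) - 0.00121 / Kd(490).
    """
    if not np.isfinite(kd) or kd <= 0:
        return np.nan
    return 0.0665 + 0.874 * kd - 0.00121 / kd


def mixed_layer_light(par_sat: float, kd_par: float, mld: float) -> float:
    """Median mixed-layer light I_ML = PAR_sat * exp(-0.5 Kd(PAR) MLD)."""
    if not (np.isfinite(par_sat) and np.isfinite(mld)) or not np.isfinite(kd_par):
        return np.nan
    return float(par_sat * np.exp(-0.5 * kd_par * mld))


def phyto_stock(z, c_phyto, chl, chl_large, const: Constants = Constants()):
    """Depth-integrated phytoplankton carbon P (mg C m-2), 0-500 m.

    C_phyto only counts where small-pool chlorophyll
    chl - chl_large - chl_refractory exceeds zero, masking refractory and
    detrital material; masked depths contribute nothing to the integral.
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(c_phyto, dtype=float)
    chl = np.asarray(chl, dtype=float)
    chl_l = np.asarray(chl_large, dtype=float) if chl_large is not None else np.zeros_like(chl)
    valid = (
        np.isfinite(c) & np.isfinite(chl)
        & ((chl - np.nan_to_num(chl_l) - const.chl_refractory) > 0)
        & (z <= 500.0)
    )
    if not np.any(valid):
        return 0.0
    masked = np.where(valid, c, 0.0)
    return float(np.trapezoid(masked, z))


@dataclass
class PhenologyMetrics:
    onset: np.datetime64 | None
    climax: np.datetime64 | None
    apex: np.datetime64 | None
    times: np.ndarray          # 5-day grid
    P: np.ndarray              # smoothed stock
    r: np.ndarray              # accumulation rate, d-1
    flagged: bool = False      # True when r never turns positive


def phenology_metrics(times, P, const: Constants = Constants()) -> PhenologyMetrics:
    """Bloom onset / climax / apex from a phytoplankton-carbon series.

    The series is linearly interpolated to a 5-day grid, smoothed with a
    30-day (7-point) running average, and r = (1/P) dP/dt taken by centred
    differences.  Apex = maximum P; climax = maximum r at or before the
    apex; onset = last negative-to-positive crossing of r preceding the
    climax (first r > 0 sample if r never goes negative before it).  A
    window shorter than 90 days is rejected.
    """
    t = np.asarray(times, dtype="datetime64[s]")
    P = np.asarray(P, dtype=float)
    order = np.argsort(t)
    t, P = t[order], P[order]
    span = (t[-1] - t[0]) / np.timedelta64(1, "D")
    if span < 90:
        raise ValueError("phenology needs at least 90 days of data")
    step = const.phenology_step_days
    days = (t - t[0]) / np.timedelta64(1, "D")
    grid = np.arange(0.0, float(days[-1]) + 1e-9, step)
    Pg = np.interp(grid, days.astype(float), P)
    k = const.phenology_smooth_points
    Ps = pd.Series(Pg).rolling(k, center=True, min_periods=1).mean().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.gradient(Ps, grid) / Ps
    r[~np.isfinite(r)] = np.nan
    grid_t = t[0] + (grid * 86400).astype("timedelta64[s]")

    i_apex = int(np.nanargmax(Ps))
    r_before = r[: i_apex + 1]
    if not np.any(np.nan_to_num(r_before, nan=-1) > 0):
        return PhenologyMetrics(None, None, grid_t[i_apex], grid_t, Ps, r, flagged=True)
    i_climax = int(np.nanargmax(np.nan_to_num(r_before, nan=-np.inf)))
    crossings = [
        i + 1
        for i in range(i_climax)
        if r[i] <= 0 < r[i + 1]
    ]
    if crossings:
        i_onset = crossings[0] if const.phenology_first_crossing else crossings[-1]
    else:
        pos = np.nonzero(np.nan_to_num(r[: i_climax + 1], nan=-1) > 0)[0]
        i_onset = int(pos[0]) if pos.size else i_climax
    return PhenologyMetrics(grid_t[i_onset], grid_t[i_climax], grid_t[i_apex],
                            grid_t, Ps, r)
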