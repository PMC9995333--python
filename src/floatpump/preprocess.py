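"""Raw profiles to analysis-ready fields.

Regridding to the common 1-m grid, the two mixed/mixing-layer depths, the
quenching (NPQ) correction of chlorophyll fluorescence, instantaneous PAR
from four-channel downwelling irradiance, carbon conversions from
backscattering, apparent oxygen utilisation and spice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from . import seawater
from .constants import Constants
from .core import Profile

__all__ = [
    "regrid_profile",
    "mld_bio",
    "mld_density",
    "compute_ipar",
    "correct_npq",
    "carbon_from_backscatter",
    "compute_aou",
    "compute_spice",
    "derive_profile",
    "DerivedProfile",
]

# Planck h * speed of light * Avogadro: J m mol-1
_HC_NA = 6.62607015e-34 * 2.99792458e8 * 6.02214076e23


def regrid_profile(z_raw, v_raw, z_grid, max_gap: float = 25.0):
    """Linear interpolation of irregular samples onto a regular depth grid.

    No extrapolation beyond the shallowest/deepest valid sample; grid points
    falling in a raw-data gap wider than ``max_gap`` metres stay masked
    (NaN).  Fewer than 2 valid samples marks the whole variable unusable.
    """
    z_raw = np.asarray(z_raw, dtype=float)
    v_raw = np.asarray(v_raw, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    ok = np.isfinite(z_raw) & np.isfinite(v_raw)
    if ok.sum() < 2:
        return np.full(z_grid.shape, np.nan)
    zs, vs = z_raw[ok], v_raw[ok]
    order = np.argsort(zs, kind="stable")
    zs, vs = zs[order], vs[order]
    out = np.interp(z_grid, zs, vs, left=np.nan, right=np.nan)
    out[(z_grid < zs[0]) | (z_grid > zs[-1])] = np.nan
    gaps = np.diff(zs)
    for i in np.nonzero(gaps > max_gap)[0]:
        inside = (z_grid > zs[i]) & (z_grid < zs[i + 1])
        out[inside] = np.nan
    return out


def _plateau_argmax(values: np.ndarray, eps: float = 1e-12) -> int:
    """Index of the maximum; a contiguous plateau of maxima collapses to its
    centre, distinct tied maxima break toward the lowest index."""
    vmax = np.nanmax(values)
    at_max = np.nonzero(values >= vmax - eps)[0]
    # first contiguous run at the maximum
    run_end = at_max[0]
    for idx in at_max[1:]:
        if idx == run_end + 1:
            run_end = idx
        else:
            break
    return int(round((at_max[0] + run_end) / 2))


def mld_bio(z, chl, const: Constants = Constants()):
    """Mixing-layer depth as the maximum vertical decrease of chlorophyll.

    The profile is smoothed with a running mean (default 5 m), the gradient
    taken by central differences, and the depth of the steepest decrease
    searched between 10 and 400 m.  A gradient everywhere below the noise
    floor (vertically uniform chlorophyll) is undefined and returns NaN.
    """
    z = np.asarray(z, dtype=float)
    chl = np.asarray(chl, dtype=float)
    ok = np.isfinite(chl)
    if ok.sum() < 30:
        return np.nan
    dz = np.median(np.diff(z))
    width = max(1, int(round(const.mld_bio_smooth / dz)))
    smooth = chl.copy()
    smooth[~ok] = np.interp(z[~ok], z[ok], chl[ok])  # fill gaps for the filter
    # despike (single-point large-particle spikes would masquerade as the
    # steepest gradient); a 3-point median is exact on monotone profiles
    smooth = pd.Series(smooth).rolling(3, center=True, min_periods=1).median().to_numpy()
    smooth = uniform_filter1d(smooth, size=width, mode="nearest")
    grad = np.gradient(smooth, z)
    decrease = -grad
    sel = (z >= const.mld_bio_zmin) & (z <= const.mld_bio_zmax) & ok
    if not np.any(sel):
        return np.nan
    decrease = np.where(sel, decrease, -np.inf)
    if np.nanmax(decrease) < const.mld_bio_noise_floor:
        return np.nan
    return float(z[_plateau_argmax(decrease)])


def mld_density(z, sigma, const: Constants = Constants()):
    """Mixed-layer depth by a density offset from a 5-m reference.

    Shallowest depth where sigma exceeds sigma(5 m) + 0.01 kg m-3.  If the
    threshold is never exceeded the deepest valid depth is returned with a
    ``fully_mixed`` flag.  Without a valid 5-m value, the shallowest valid
    depth at or above 10 m serves as reference.
    """
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    ok = np.isfinite(sigma)
    if not np.any(ok):
        return np.nan, False
    iref = np.argmin(np.abs(z - const.mld_density_ref_depth))
    if not ok[iref] or abs(z[iref] - const.mld_density_ref_depth) > 1.0:
        shallow = np.nonzero(ok & (z <= 10.0))[0]
        if shallow.size == 0:
            return np.nan, False
        iref = shallow[0]
    ref = sigma[iref]
    below = ok & (z >= z[iref])
    exceeded = below & (sigma > ref + const.mld_density_threshold)
    if not np.any(exceeded):
        return float(z[ok][-1]), True
    return float(z[np.nonzero(exceeded)[0][0]]), False


def compute_ipar(z, ed, wavelengths=(412.0, 443.0, 490.0, 550.0), quantum: bool = True):
    """Instantaneous PAR profile from multispectral downwelling irradiance.

    At each depth a cubic spline is drawn through the measured channels plus
    a pinned zero at 1000 nm, evaluated at 1-nm steps, clipped at zero, and
    integrated over 400-700 nm.  With ``quantum=True`` (default) the energy
    spectrum is converted to quanta per nm (lambda / h c N_A) before
    integration, yielding umol photons m-2 s-1; otherwise W m-2.
    Depths with fewer than 3 valid channels stay masked.
    """
    z = np.asarray(z, dtype=float)
    ed = np.asarray(ed, dtype=float)  # (n_wl, n_depth)
    wl = np.asarray(wavelengths, dtype=float)
    lam = np.arange(400.0, 701.0)
    out = np.full(z.shape, np.nan)
    for i in range(z.size):
        spec = ed[:, i]
        ok = np.isfinite(spec)
        if ok.sum() < 3:
            continue
        if np.max(spec[ok]) < 1e-7:  # light long gone; spare the spline
            out[i] = 0.0
            continue
        knots_x = np.append(wl[ok], 1000.0)
        knots_y = np.append(spec[ok], 0.0)
        spline = CubicSpline(knots_x, knots_y, extrapolate=True)
        e = np.clip(spline(lam), 0.0, None)  # W m-2 nm-1
        if quantum:
            q = e * (lam * 1e-9) / _HC_NA * 1e6  # umol photons m-2 s-1 nm-1
            out[i] = np.trapezoid(q, lam)
        else:
            out[i] = np.trapezoid(e, lam)
    return out


def correct_npq(z, chl, ipar, mld_dens, sun_elevation, const: Constants = Constants()):
    """Quenching correction of daytime chlorophyll fluorescence.

    For profiles with sun elevation > 5 deg, the maximum chlorophyll above
    the density mixed-layer depth is extended to the surface, provided that
    maximum sits shallower than the 15 umol photons m-2 s-1 isolume.  Night
    profiles and profiles failing the isolume condition pass unchanged.

    Returns ``(chl_corrected, correction_depth)`` where the depth is NaN when
    no correction was applied.
    """
    z = np.asarray(z, dtype=float)
    chl = np.asarray(chl, dtype=float)
    if sun_elevation <= const.npq_min_sun_elevation or not np.isfinite(mld_dens):
        return chl.copy(), np.nan
    above = np.isfinite(chl) & (z <= mld_dens)
    if not np.any(above):
        return chl.copy(), np.nan
    idx_above = np.nonzero(above)[0]
    imax = idx_above[np.nanargmax(chl[idx_above])]
    z_max = z[imax]
    # isolume: shallowest depth where ipar drops below threshold
    if ipar is None or not np.any(np.isfinite(ipar)):
        return chl.copy(), np.nan
    ipar = np.asarray(ipar, dtype=float)
    lit = np.isfinite(ipar) & (ipar >= const.npq_isolume)
    z_isolume = z[np.nonzero(lit)[0][-1]] if np.any(lit) else 0.0
    if z_max >= z_isolume:
        return chl.copy(), np.nan
    out = chl.copy()
    out[z < z_max] = chl[imax]
    return out, float(z_max)


def carbon_from_backscatter(bbp, channel: int, const: Constants = Constants()):
    """POC (from bbp700) or phytoplankton carbon (from bbp470), mg C m-3.

    Exact affine maps; negative backscattering is masked.  Uncertainty in
    the 700-nm coefficients is handled downstream by the Monte Carlo engine.
    """
    bbp = np.asarray(bbp, dtype=float)
    if channel == 700:
        out = const.q_bbp_poc.mean * bbp + const.poc_intercept.mean
    elif channel == 470:
        out = const.c_phyto_slope * bbp + const.c_phyto_intercept
    else:
        raise ValueError("channel must be 470 or 700")
    return np.where(bbp < 0, np.nan, out)


def compute_aou(o2, T, S):
    """Apparent oxygen utilisation: saturation minus observed, umol kg-1.

    Expects gain-corrected oxygen.  Supersaturated water gives negative AOU.
    """
    return seawater.o2_saturation(T, S) - np.asarray(o2, dtype=float)


def compute_spice(T, S):
    """Surface-referenced spice; warmer-saltier on an isopycnal => larger."""
    return seawater.spiciness(T, S)


@dataclass
class DerivedProfile:
    """A profile plus every derived field the estimators consume."""

    profile: Profile
    chl_corrected: np.ndarray
    ipar: np.ndarray
    poc: np.ndarray
    c_phyto: np.ndarray
    aou: np.ndarray
    spice: np.ndarray
    mld_bio: float
    mld_density: float
    fully_mixed: bool
    sun_elevation: float
    npq_depth: float  # NaN when no quenching correction was applied

    @property
    def time(self):
        return self.profile.time

    @property
    def z(self):
        return self.profile.z


def derive_profile(profile: Profile, const: Constants = Constants(),
                   with_light: bool = True) -> DerivedProfile:
    """Run the full per-profile derivation chain in dependency order.

    ``with_light=False`` skips the iPAR spectra and the NPQ correction (the
    costly stages) for callers that only need the dark-side fields.
    """
    p = profile
    sigma = p.sigma
    if sigma is None and p.T is not None and p.S is not None:
        sigma = seawater.density_anomaly(p.T, p.S)
    mldd, fully_mixed = mld_density(p.z, sigma, const) if sigma is not None else (np.nan, False)
    ipar = (
        compute_ipar(p.z, p.ed, p.ed_wavelengths, const.ipar_quantum)
        if (p.ed is not None and with_light)
        else np.full(p.z.shape, np.nan)
    )
    elev = float(seawater.solar_elevation(p.time, p.lat, p.lon))
    if with_light:
        chl_corr, npq_depth = correct_npq(p.z, p.chl, ipar, mldd, elev, const)
    else:
        chl_corr, npq_depth = (p.chl.copy() if p.chl is not None else None), np.nan
    poc = carbon_from_backscatter(p.bbp700, 700, const) if p.bbp700 is not None else None
    cphy = carbon_from_backscatter(p.bbp470, 470, const) if p.bbp470 is not None else None
    # optode gain is applied at read time (io module); o2 here is calibrated
    aou = compute_aou(p.o2, p.T, p.S) if (p.o2 is not None and p.T is not None) else None
    spice = compute_spice(p.T, p.S) if p.T is not None else None
    mldb = mld_bio(p.z, chl_corr, const)
    return DerivedProfile(
        profile=p,
        chl_corrected=chl_corr,
        ipar=ipar,
        poc=poc,
        c_phyto=cphy,
        aou=aou,
        spice=spice,
        mld_bio=mldb,
        mld_density=mldd,
        fully_mixed=fully_mixed,
        sun_elevation=elev,
        npq_depth=npq_depth,
    )
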