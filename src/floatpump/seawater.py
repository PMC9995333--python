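"""Seawater state functions and solar geometry.

Small, self-contained implementations of the published formulas the pipeline
needs:

* surface-referenced density (EOS-80 one-atmosphere polynomial of
  Millero & Poisson, 1981) for the potential density anomaly sigma-theta;
* oxygen solubility at saturation (Garcia & Gordon, 1992, Benson-Krause
  coefficients, umol kg-1) for apparent oxygen utilisation;
* spiciness (Flament, 2002 polynomial, surface referenced) -- the
  density-compensated temperature/salinity state variable whose subsurface
  anomalies trace recently subducted water;
* solar elevation (NOAA solar position algorithm, ~0.01 deg accuracy) used
  to gate the non-photochemical-quenching correction to daytime profiles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "density_anomaly",
    "o2_saturation",
    "spiciness",
    "solar_elevation",
]


def density_anomaly(T, S):
    """Potential density anomaly sigma-theta (kg m-3) at 0 dbar.

    One-atmosphere EOS-80 polynomial rho(S, T, 0) - 1000.  In-situ
    temperature is used in place of potential temperature, an approximation
    accurate to a few 1e-3 kg m-3 over the upper 500 m.
    Check value: rho(S=35, T=5) = 1027.67547 kg m-3.
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = (
        8.24493e-1
        - 4.0899e-3 * T
        + 7.6438e-5 * T**2
        - 8.2467e-7 * T**3
        + 5.3875e-9 * T**4
    )
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    with np.errstate(invalid="ignore"):
        rho = rho_w + A * S + B * S * np.sqrt(np.abs(S)) + C * S**2
    return rho - 1000.0


# Garcia & Gordon (1992) combined fit, Benson & Krause data, umol kg-1.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_saturation(T, S):
    """Oxygen concentration at saturation with the atmosphere (umol kg-1)."""
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    Ts = np.log((298.15 - T) / (273.15 + T))
    lnC = np.zeros_like(Ts)
    for i, a in enumerate(_GG_A):
        lnC = lnC + a * Ts**i
    poly_b = np.zeros_like(Ts)
    for i, b in enumerate(_GG_B):
        poly_b = poly_b + b * Ts**i
    lnC = lnC + S * poly_b + _GG_C0 * S**2
    return np.exp(lnC)


# Flament (2002) spiciness polynomial, b[i][j] multiplying theta^i (s-35)^j.
_FLAMENT_B = np.array(
    [
        [0.0, 7.7442e-1, -5.85e-3, -9.84e-4, -2.06e-4],
        [5.1655e-2, 2.034e-3, -2.742e-4, -8.5e-6, 1.36e-5],
        [6.64783e-3, -2.4681e-4, -1.428e-5, 3.337e-5, 7.894e-6],
        [-5.4023e-5, 7.326e-6, 7.0036e-6, -3.0412e-6, -1.0853e-6],
        [3.949e-7, -3.029e-8, -3.8209e-7, 1.0012e-7, 4.7133e-8],
        [-6.36e-10, -1.309e-9, 6.048e-9, -1.1409e-9, -6.676e-10],
    ]
)


def spiciness(T, S):
    """Surface-referenced spiciness pi(theta, s) (kg m-3-like units).

    Flament (2002) polynomial: orthogonal to isopycnals in the mean, larger
    for warmer/saltier water along an isopycnal, pinned to pi(0 degC, 35) = 0.
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    ds = S - 35.0
    out = np.zeros(np.broadcast(T, S).shape, dtype=float)
    for i in range(6):
        for j in range(5):
            b = _FLAMENT_B[i, j]
            if b != 0.0:
                out = out + b * T**i * ds**j
    return out


def solar_elevation(time, lat, lon):
    """Sun elevation angle above the horizon (degrees).

    NOAA solar position algorithm (Meeus-based); adequate to decide whether
    the sun is more than a few degrees up.  ``time`` is a UTC
    ``numpy.datetime64`` (or anything convertible), ``lat``/``lon`` degrees
    (east positive).
    """
    t = np.asarray(time, dtype="datetime64[s]")
    # Julian day from the Unix epoch (1970-01-01 = JD 2440587.5)
    jd = t.astype("int64") / 86400.0 + 2440587.5
    jc = (jd - 2451545.0) / 36525.0  # Julian century from J2000

    gml = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    rad = np.pi / 180.0
    eq_ctr = (
        np.sin(gma * rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * gma * rad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * gma * rad) * 0.000289
    )
    true_long = gml + eq_ctr
    app_long = true_long - 0.00569 - 0.00478 * np.sin((125.04 - 1934.136 * jc) * rad)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos((125.04 - 1934.136 * jc) * rad)
    decl = np.arcsin(np.sin(obliq * rad) * np.sin(app_long * rad)) / rad

    vary = np.tan(obliq / 2.0 * rad) ** 2
    eq_time = 4.0 / rad * (
        vary * np.sin(2 * gml * rad)
        - 2 * ecc * np.sin(gma * rad)
        + 4 * ecc * vary * np.sin(gma * rad) * np.cos(2 * gml * rad)
        - 0.5 * vary**2 * np.sin(4 * gml * rad)
        - 1.25 * ecc**2 * np.sin(2 * gma * rad)
    )  # minutes

    seconds_of_day = np.mod(t.astype("int64"), 86400)
    true_solar_min = np.mod(seconds_of_day / 60.0 + eq_time + 4.0 * np.asarray(lon, float), 1440.0)
    hour_angle = np.where(
        true_solar_min / 4.0 < 0.0,
        true_solar_min / 4.0 + 180.0,
        true_solar_min / 4.0 - 180.0,
    )
    lat_r = np.asarray(lat, float) * rad
    cos_zen = np.sin(lat_r) * np.sin(decl * rad) + np.cos(lat_r) * np.cos(decl * rad) * np.cos(hour_angle * rad)
    zen = np.arccos(np.clip(cos_zen, -1.0, 1.0)) / rad
    return 90.0 - zen
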