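"""Shared constants and run configuration.

Every empirically calibrated coefficient used by the flux estimators is an
:class:`Uncertain` pair ``(mean, sd)`` so that it can be pushed through the
Monte Carlo engine in :mod:`floatpump.core`.  Defaults are the published
calibrations the analysis relies on (bbp-to-POC and attenuance-to-POC
conversions, bulk sinking speeds of large particles, mesopelagic respiration).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

log = logging.getLogger("floatpump")


class Uncertain(NamedTuple):
    """A scalar with a one-sigma uncertainty (normal errors assumed)."""

    mean: float
    sd: float = 0.0

    def __str__(self) -> str:  # config round-trip format
        return f"{self.mean},{self.sd}"

    @classmethod
    def parse(cls, text: str) -> "Uncertain":
        parts = [float(p) for p in str(text).split(",")]
        if len(parts) == 1:
            return cls(parts[0], 0.0)
        if len(parts) != 2 or parts[1] < 0:
            raise ValueError(f"cannot parse Uncertain from {text!r}")
        return cls(parts[0], parts[1])


#: quasi-Lagrangian windows over which water masses stayed contiguous and
#: seasonal integrals are meaningful (ISO dates, inclusive start / end).
DEFAULT_WINDOWS = (
    ("2016-09-24", "2017-05-22"),
    ("2017-10-10", "2018-06-07"),
    ("2018-11-05", "2019-05-01"),
)


@dataclass
class Constants:
    """Every tunable constant of the pipeline, with calibrated uncertainties.

    Units: sinking speeds in m d-1, carbon conversions map m-1 (backscattering)
    to mg C m-3, the attenuance-flux conversion maps m2 m-2 d-1 to
    mg C m-2 d-1, respiration R in mg C m-3 d-1 (volumetric, so that
    dt = dPOC / R is in days), depths in m.
    """

    # gravitational pump: bulk sinking speeds of large particles
    w_bbl: Uncertain = Uncertain(74.0, 45.0)
    w_chl: Uncertain = Uncertain(98.0, 64.0)

    # bbp700 -> POC (Southern-Ocean calibration); slope only for spike pools
    q_bbp_poc: Uncertain = Uncertain(3.12e4, 2.47e3)
    poc_intercept: Uncertain = Uncertain(3.04, 6.78)

    # bbp470 -> phytoplankton carbon
    c_phyto_slope: float = 12.128e3
    c_phyto_intercept: float = 0.59

    # optical sediment trap attenuance-flux -> carbon-flux conversion
    ost_slope: Uncertain = Uncertain(2133.0, 173.0)
    ost_intercept: Uncertain = Uncertain(1.4, 5.6)

    # mesopelagic respiration rate (volumetric; see module docs)
    respiration: Uncertain = Uncertain(0.33, 0.16)

    # refractory chlorophyll background used by the phenology mask (mg m-3)
    chl_refractory: float = 0.3

    # eddy-subduction detection thresholds
    esp_aou_threshold: float = -5.0      # umol kg-1
    esp_spice_threshold: float = -0.05
    esp_poc_threshold: float = 0.0       # mg C m-3
    esp_grid: float = 5.0                # m, anomaly grid spacing
    esp_half_window: int = 10            # bins each side of the running median
    esp_zmax: float = 500.0              # m, deepest search depth
    esp_min_bins: int = 30               # minimum valid 5-m bins below MLD

    # Monte Carlo engine
    mc_iterations: int = 5000

    # mixed layer pump
    z_floor: float = 100.0               # m, productive-layer floor
    mlp_window_days: float = 20.0        # centred moving-sum span

    # oxygen optode air-calibration gain
    o2_gain: float = 1.0557

    # binning
    bin_width_days: float = 10.0

    # NPQ correction
    npq_isolume: float = 15.0            # umol photons m-2 s-1
    npq_min_sun_elevation: float = 5.0   # degrees

    # density mixed-layer depth (NPQ correction reference)
    mld_density_threshold: float = 0.01  # kg m-3
    mld_density_ref_depth: float = 5.0   # m

    # biological mixing-layer depth
    mld_bio_smooth: float = 5.0          # m running-mean length
    mld_bio_zmin: float = 10.0
    mld_bio_zmax: float = 400.0
    mld_bio_noise_floor: float = 1e-4    # mg m-3 m-1

    # regridding
    regrid_gap_limit: float = 25.0       # m

    # optical spike decomposition
    spike_window: int = 11               # points (~11 m at 1-m gridding)
    blank_span: float = 50.0             # deepest span used for the blank
    blank_min_depth: float = 200.0       # shallower profiles fall back
    default_chl_blank: float = 0.012     # mg m-3 fallback blanks
    default_bbp_blank: float = 4.0e-4    # m-1

    # spike-flux stratum below the mixing layer
    spike_stratum: float = 100.0         # m

    # optical sediment trap cleaning / segmentation
    ost_min_duration_h: float = 24.0
    ost_drop_first: int = 3
    ost_spike_rise: float = 0.002        # m2 m-2 per sample (hourly cadence)
    ost_spike_lookahead: int = 3
    ost_median_window: int = 5
    ost_min_points: int = 10
    ost_fit_tol: float = 5e-4            # m2 m-2 max |residual| per segment
    ost_min_segment: int = 3
    ost_clamp_negative: bool = False

    # iron-stress index
    alpha_npq_ipar_min: float = 15.0
    alpha_npq_ipar_max: float = 75.0
    alpha_npq_r2_min: float = 0.8

    # phenology
    phenology_step_days: float = 5.0
    phenology_smooth_points: int = 7     # 30-d running average at 5-d step
    phenology_first_crossing: bool = False

    # iPAR spectral integration: quantum (default) or pure energy units
    ipar_quantum: bool = True

    # quasi-Lagrangian windows, ISO date pairs
    windows: tuple = DEFAULT_WINDOWS

    def log_values(self) -> None:
        """Log every constant (estimators call this so runs are auditable)."""
        for f in dataclasses.fields(self):
            log.info("constant %s = %s", f.name, getattr(self, f.name))

    # -- plain-text key = value config round trip ---------------------------

    def to_config(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "windows":
                v = ";".join(f"{a}:{b}" for a, b in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "Constants":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if key == "windows":
                kwargs[key] = tuple(
                    tuple(pair.split(":")) for pair in val.split(";") if pair
                )
            elif isinstance(default, Uncertain):
                kwargs[key] = Uncertain.parse(val)
            elif isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)
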