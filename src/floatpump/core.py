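"""Shared data model, 10-day binning, and the Monte Carlo uncertainty engine.

Flux series are represented as :class:`pandas.DataFrame` tables with the
canonical columns ``bin_start, bin_end, median, q25, q75, n_obs, pathway``
(one row per 10-day bin; an empty bin is kept with ``n_obs = 0`` and missing
statistics).  Quartiles use linear interpolation between order statistics
(numpy's default), and bins are left-closed/right-open, anchored at the
series start (or an explicit anchor such as the first profile date of a
quasi-Lagrangian window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import Uncertain

FLUX_COLUMNS = ["bin_start", "bin_end", "median", "q25", "q75", "n_obs", "pathway"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Profile:
    """One float ascent on a common 1-m depth grid.

    Depths are positive down and strictly increasing; masked (bad or absent)
    samples are NaN, never deleted.  ``ed`` rows follow ``ed_wavelengths``.
    """

    time: np.datetime64
    lat: float
    lon: float
    z: np.ndarray
    T: np.ndarray = None
    S: np.ndarray = None
    sigma: np.ndarray = None
    chl: np.ndarray = None
    bbp470: np.ndarray = None
    bbp700: np.ndarray = None
    cp660: np.ndarray = None
    o2: np.ndarray = None
    ed: np.ndarray = None  # shape (n_wavelengths, len(z))
    ed_wavelengths: tuple = (412.0, 443.0, 490.0, 550.0)
    par_sat: float = np.nan  # satellite-style daily surface PAR scalar
    profile_id: int = -1

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("profile depth grid must be strictly increasing")
        n = self.z.size
        for name in ("T", "S", "sigma", "chl", "bbp470", "bbp700", "cp660", "o2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} does not share the depth grid")
                setattr(self, name, v)
        if self.ed is not None:
            self.ed = np.asarray(self.ed, dtype=float)
            if self.ed.shape != (len(self.ed_wavelengths), n):
                raise ValueError("ed must be (n_wavelengths, n_depths)")


@dataclass
class ParkingSeries:
    """Hourly attenuance record at the drift depth between two profiles."""

    start: np.datetime64
    end: np.datetime64
    t: np.ndarray          # hours since phase start
    atn: np.ndarray        # particle attenuance, m2 m-2
    depth: float = 300.0
    phase_id: int = -1

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.atn = np.asarray(self.atn, dtype=float)
        if self.t.shape != self.atn.shape:
            raise ValueError("t and atn must align")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("parking sample times must be strictly increasing")

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / np.timedelta64(1, "h")


# ---------------------------------------------------------------------------
# binning


def _as_days(times, anchor=None):
    times = np.asarray(times)
    if np.issubdtype(times.dtype, np.datetime64):
        anchor = np.datetime64(anchor) if anchor is not None else times.min()
        days = (times - anchor) / np.timedelta64(1, "D")
        return days.astype(float), anchor
    times = times.astype(float)
    anchor = float(anchor) if anchor is not None else float(times.min())
    return times - anchor, anchor


def bin_statistics(
    times,
    values,
    bin_width: float = 10.0,
    anchor=None,
    t_end=None,
    reduce: str = "quartiles",
) -> pd.DataFrame:
    """Median and quartiles of ``values`` in contiguous time bins.

    Bins are left-closed/right-open, ``bin_width`` days wide, anchored at
    ``anchor`` (default: first sample).  Empty bins are emitted with
    ``n_obs = 0`` and NaN statistics, never dropped.  ``reduce='mean'``
    additionally reports the bin mean and standard deviation (columns
    ``mean``/``sd``), used by estimators whose Monte Carlo treats the bin
    content as a normally distributed population.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    days, anchor0 = _as_days(times, anchor)
    if t_end is not None:
        end_days, _ = _as_days(np.asarray([t_end]), anchor0)
        span = float(end_days[0])
    else:
        span = float(days.max()) if days.size else bin_width
    n_bins = max(1, int(np.ceil(max(span, 1e-9) / bin_width)))
    if span > 0 and span % bin_width == 0 and t_end is None:
        n_bins = max(1, int(np.ceil((span + 1e-9) / bin_width)))

    rows = []
    datelike = isinstance(anchor0, np.datetime64)
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        sel = (days >= lo) & (days < hi)
        if k == n_bins - 1:  # include a sample landing exactly on the end
            sel |= days == hi
        v = values[sel]
        v = v[np.isfinite(v)]
        if datelike:
            b0 = anchor0 + np.timedelta64(int(lo * 24 * 3600), "s")
            b1 = anchor0 + np.timedelta64(int(hi * 24 * 3600), "s")
        else:
            b0, b1 = anchor0 + lo, anchor0 + hi
        row = {"bin_start": b0, "bin_end": b1, "n_obs": int(v.size)}
        if v.size:
            row["median"] = float(np.median(v))
            row["q25"] = float(np.percentile(v, 25))
            row["q75"] = float(np.percentile(v, 75))
            if reduce == "mean":
                row["mean"] = float(np.mean(v))
                row["sd"] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        else:
            row.update(median=np.nan, q25=np.nan, q75=np.nan)
            if reduce == "mean":
                row.update(mean=np.nan, sd=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte Carlo engine


@dataclass
class MCSummary:
    median: float
    q25: float
    q75: float
    n_iter: int
    n_rejected: int = 0

    def astuple(self):
        return (self.median, self.q25, self.q75)


def propagate_uncertainty(
    fn: Callable[..., np.ndarray],
    params: Mapping[str, Uncertain | tuple],
    n_iter: int = 5000,
    seed: int | np.random.Generator = 0,
    reject: Callable[..., np.ndarray] | None = None,
) -> MCSummary:
    """Push normally distributed parameters through ``fn`` by Monte Carlo.

    ``fn`` receives one numpy array per parameter (all of length ``n_iter``)
    and must be vectorised.  Draws are independent normals per parameter;
    nonnegativity is *not* enforced (draws of physically nonnegative
    quantities may go negative; supply ``reject`` to exclude them).
    ``reject`` receives the same arrays and returns a boolean mask of draws
    to discard; the count is reported.  A fixed seed makes the triple
    bit-reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {}
    for name, p in params.items():
        mean, sd = (p.mean, p.sd) if isinstance(p, Uncertain) else (float(p[0]), float(p[1]))
        if sd < 0:
            raise ValueError(f"negative sd for parameter {name!r}")
        draws[name] = rng.normal(mean, sd, size=n_iter) if sd > 0 else np.full(n_iter, mean)
    n_rej = 0
    if reject is not None:
        bad = np.asarray(reject(**draws), dtype=bool)
        n_rej = int(bad.sum())
        draws = {k: v[~bad] for k, v in draws.items()}
    if next(iter(draws.values())).size == 0:
        return MCSummary(np.nan, np.nan, np.nan, n_iter, n_rej)
    out = np.asarray(fn(**draws), dtype=float)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "fn undefined on a Monte Carlo draw and no rejection rule supplied"
        )
    return MCSummary(
        float(np.median(out)),
        float(np.percentile(out, 25)),
        float(np.percentile(out, 75)),
        n_iter,
        n_rej,
    )


def flux_row(bin_start, bin_end, summary: MCSummary, n_obs: int, pathway: str) -> dict:
    """One FluxEstimate record (see module docstring for the table schema)."""
    return {
        "bin_start": bin_start,
        "bin_end": bin_end,
        "median": summary.median,
        "q25": summary.q25,
        "q75": summary.q75,
        "n_obs": n_obs,
        "pathway": pathway,
    }


def empty_flux_row(bin_start, bin_end, pathway: str) -> dict:
    return {
        "bin_start": bin_start,
        "bin_end": bin_end,
        "median": np.nan,
        "q25": np.nan,
        "q75": np.nan,
        "n_obs": 0,
        "pathway": pathway,
    }
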