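"""End-to-end orchestration: profiles in, flux report out.

Runs the per-profile derivations, the optical decomposition, and all four
pathway estimators (spike fluxes, optical sediment trap, mixed layer pump,
eddy subduction pump) plus particle size and photophysiology over
quasi-Lagrangian windows, returning a :class:`RunReport` of binned flux
tables, annual integrals and diagnostics.  Deterministic for a given
(mission, constants, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import esp as esp_mod
from . import mlp as mlp_mod
from . import ost as ost_mod
from . import photophys, preprocess, size, spikes
from .constants import Constants, Uncertain
from .core import propagate_uncertainty

log = logging.getLogger("floatpump")

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    windows: list                      # (label, start, end)
    fluxes: pd.DataFrame               # all pathways, all windows, 10-d bins
    size: pd.DataFrame                 # particle-size series
    esp_features: pd.DataFrame         # detected feature catalog
    mlp_events: pd.DataFrame
    ost_phases: pd.DataFrame           # per-phase diagnostics
    annual_integrals: pd.DataFrame     # g C m-2 per (window, pathway)
    phenology: pd.DataFrame            # onset/climax/apex per window
    photo: pd.DataFrame                # per-profile alpha_NPQ, kd, I_ML
    diagnostics: dict

    def flux_table(self, pathway: str) -> pd.DataFrame:
        return self.fluxes[self.fluxes["pathway"] == pathway].reset_index(drop=True)


def _effective_windows(times, const: Constants):
    t0, t1 = times.min(), times.max()
    wins = []
    for i, (a, b) in enumerate(const.windows):
        wa, wb = np.datetime64(a, "s"), np.datetime64(b, "s")
        if wa <= t1 and wb >= t0:
            wins.append((f"window_{i + 1}", max(wa, t0), min(wb, t1)))
    if not wins:
        wins = [("window_1", t0, t1)]
    return wins


def _integral_g(flux_df: pd.DataFrame, bin_width: float) -> float:
    """Time integral of a binned flux series, g C m-2 (NaN bins skipped)."""
    med = flux_df["median"].to_numpy(dtype=float)
    return float(np.nansum(med) * bin_width / 1000.0)


def run_pipeline(mission, const: Constants = Constants(), seed: int = 0,
                 estimators: tuple = ("spikes", "size", "ost", "mlp", "esp", "photo"),
                 ) -> RunReport:
    """Run the full multi-pathway analysis on a mission.

    ``estimators`` can disable individual pathways; each estimator draws its
    Monte Carlo from an independent seed stream so disabling one never
    changes another's numbers.
    """
    const.log_values()
    diagnostics = {"skipped_profiles": [], "mc_rejections": {}, "missing": []}

    derived = [preprocess.derive_profile(p, const) for p in mission.profiles]
    times = np.array([d.time for d in derived], dtype="datetime64[s]")
    windows = _effective_windows(times, const)

    # per-profile optical decomposition (chl and bbp pools share the method)
    comp_chl, comp_bbp = [], []
    for d in derived:
        comp_chl.append(spikes.decompose_optical(
            d.z, d.chl_corrected, const.default_chl_blank, const))
        comp_bbp.append(spikes.decompose_optical(
            d.z, d.profile.bbp700, const.default_bbp_blank, const))

    seeds = {name: 1000 + 100 * k for k, name in
             enumerate(("spikes", "size", "ost", "mlp", "esp", "photo"))}
    base_seed = int(seed)

    flux_frames, annual_rows, phen_rows = [], [], []
    size_frames = []
    esp_feature_rows = []
    mlp_event_frames = []
    ost_table = (ost_mod.process_parking_series(mission.parkings, const)
                 if mission.parkings else pd.DataFrame())

    for label, w0, w1 in windows:
        sel = (times >= w0) & (times <= w1)
        idx = np.nonzero(sel)[0]
        if idx.size < 2:
            continue
        anchor, t_end = times[idx[0]], times[idx[-1]]

        if "spikes" in estimators:
            for kind, comps in (("chl", comp_chl), ("poc", comp_bbp)):
                try:
                    means = spikes.stratum_bin_means(
                        times[idx], [derived[i].z for i in idx],
                        [comps[i].large for i in idx],
                        [derived[i].mld_bio for i in idx],
                        const.bin_width_days, const.spike_stratum,
                        anchor=anchor, t_end=t_end)
                except ValueError:
                    diagnostics["missing"].append((label, f"F_{kind}_spike"))
                    continue
                tbl = spikes.spike_flux(means, kind, const,
                                        seed=base_seed + seeds["spikes"])
                tbl["window"] = label
                flux_frames.append(tbl)
                annual_rows.append({"window": label, "pathway": f"F_{kind}_spike",
                                    "g_C_m2": _integral_g(tbl, const.bin_width_days)})

        if "size" in estimators:
            st, sd_ = [], []
            for i in idx:
                d = derived[i]
                upper = d.z <= 50.0
                for sig, geom in ((d.profile.cp660, size.CP_PRESET),
                                  (d.profile.bbp470, size.BBP_PRESET),
                                  (d.profile.bbp700, size.BBP_PRESET)):
                    if sig is None:
                        continue
                    est = size.mean_diameter_profile(sig[upper], geom)
                    if np.isfinite(est):
                        st.append(times[i])
                        sd_.append(est)
            if st:
                tbl = size.size_timeseries(np.array(st), sd_, const.bin_width_days,
                                           anchor=anchor, t_end=t_end)
                tbl["window"] = label
                size_frames.append(tbl)

        if "ost" in estimators and len(ost_table):
            ph = ost_table[~ost_table["rejected"]]
            ph = ph[(ph["start"].values >= w0) & (ph["end"].values <= w1)]
            if len(ph):
                mid = ph["start"] + (ph["end"] - ph["start"]) / 2
                for comp_name, col in (("continuous", "fatn_continuous"),
                                       ("pulsed", "fatn_pulsed")):
                    tbl = ost_mod.atn_to_carbon(
                        mid.to_numpy(), ph[col].to_numpy(),
                        f"F_OST_{comp_name}", const,
                        seed=base_seed + seeds["ost"],
                        anchor=anchor, t_end=t_end)
                    tbl["window"] = label
                    flux_frames.append(tbl)
                    annual_rows.append({
                        "window": label, "pathway": f"F_OST_{comp_name}",
                        "g_C_m2": _integral_g(tbl, const.bin_width_days)})
        elif "ost" in estimators:
            diagnostics["missing"].append((label, "F_OST"))

        if "mlp" in estimators:
            events = []
            for a, b in zip(idx[:-1], idx[1:]):
                da, db = derived[a], derived[b]
                if not (np.isfinite(da.mld_bio) and np.isfinite(db.mld_bio)):
                    diagnostics["skipped_profiles"].append((label, int(a), "mld_bio undefined"))
                    continue
                events.append(mlp_mod.exchange_stock(
                    da.z, da.profile.bbp700, da.time, db.time,
                    da.mld_bio, db.mld_bio, const))
            if events:
                tbl = mlp_mod.mlp_flux_series(events, const,
                                              seed=base_seed + seeds["mlp"],
                                              anchor=anchor, t_end=t_end)
                tbl["window"] = label
                flux_frames.append(tbl.drop(columns=["low_confidence"]))
                summary = mlp_mod.annual_integral(events, const,
                                                  seed=base_seed + seeds["mlp"] + 1)
                annual_rows.append({"window": label, "pathway": "F_MLP",
                                    "g_C_m2": summary.median})
                ev_frame = mlp_mod.events_frame(events)
                ev_frame["window"] = label
                mlp_event_frames.append(ev_frame)

        if "esp" in estimators:
            _run_esp(derived, idx, times, anchor, t_end, const,
                     base_seed + seeds["esp"], label,
                     esp_feature_rows, flux_frames, diagnostics)

        if "photo" in estimators:
            phot = _run_photo(derived, comp_chl, idx, const)
            phot["window"] = label
            if "photo_table" not in diagnostics:
                diagnostics["photo_table"] = []
            diagnostics["photo_table"].append(phot)
            P_rows = [(times[i],
                       photophys.phyto_stock(derived[i].z, derived[i].c_phyto,
                                             derived[i].chl_corrected,
                                             comp_chl[i].large, const))
                      for i in idx]
            try:
                phen = photophys.phenology_metrics(
                    [t for t, _ in P_rows], [p for _, p in P_rows], const)
                phen_rows.append({"window": label, "onset": phen.onset,
                                  "climax": phen.climax, "apex": phen.apex,
                                  "flagged": phen.flagged})
            except ValueError as exc:
                phen_rows.append({"window": label, "onset": None, "climax": None,
                                  "apex": None, "flagged": True})
                diagnostics["missing"].append((label, f"phenology: {exc}"))

    photo_table = (pd.concat(diagnostics.pop("photo_table"), ignore_index=True)
                   if diagnostics.get("photo_table") else pd.DataFrame())
    return RunReport(
        windows=windows,
        fluxes=(pd.concat(flux_frames, ignore_index=True)
                if flux_frames else pd.DataFrame()),
        size=(pd.concat(size_frames, ignore_index=True)
              if size_frames else pd.DataFrame()),
        esp_features=pd.DataFrame(esp_feature_rows),
        mlp_events=(pd.concat(mlp_event_frames, ignore_index=True)
                    if mlp_event_frames else pd.DataFrame()),
        ost_phases=ost_table,
        annual_integrals=pd.DataFrame(annual_rows),
        phenology=pd.DataFrame(phen_rows),
        photo=photo_table,
        diagnostics=diagnostics,
    )


def _ml_mean(d, values):
    sel = (d.z <= d.mld_bio) & np.isfinite(values)
    return float(np.mean(values[sel])) if np.any(sel) else np.nan


def _run_esp(derived, idx, times, anchor, t_end, const, seed, label,
             feature_rows, flux_frames, diagnostics):
    z5 = np.arange(0.0, const.esp_zmax + 1e-9, const.esp_grid)
    features = []
    for i in idx:
        d = derived[i]
        if d.aou is None or d.spice is None or d.poc is None or not np.isfinite(d.mld_bio):
            diagnostics["skipped_profiles"].append((label, int(i), "esp inputs missing"))
            continue

        def to5(v):
            ok = np.isfinite(v)
            return np.interp(z5, d.z[ok], v[ok], left=np.nan, right=np.nan) if ok.sum() > 1 else np.full(z5.shape, np.nan)

        anoms = esp_mod.profile_anomalies(z5, to5(d.aou), to5(d.spice), to5(d.poc),
                                          d.mld_bio, const)
        if anoms is None:
            diagnostics["skipped_profiles"].append((label, int(i), "esp: too few bins"))
            continue
        feat = esp_mod.detect_esp_feature(times[i], z5, anoms, to5(d.poc), const)
        if feat is not None:
            features.append((i, feat))

    # fill bin-level context (mixed-layer POC and MLD statistics), compute
    # the flux draws per feature, and pool features per 10-day bin
    bw = const.bin_width_days
    rng = np.random.default_rng(seed)
    day_of = ((times - anchor) / np.timedelta64(1, "D")).astype(float)
    draws_by_bin, nobs_by_bin = {}, {}
    for i, feat in features:
        k = int(day_of[i] // bw)
        in_bin = (day_of >= k * bw) & (day_of < (k + 1) * bw)
        poc_ml = [_ml_mean(derived[j], derived[j].poc) for j in np.nonzero(in_bin)[0]]
        mlds = [derived[j].mld_bio for j in np.nonzero(in_bin)[0]]
        poc_ml = [v for v in poc_ml if np.isfinite(v)]
        mlds = [v for v in mlds if np.isfinite(v)]
        feat.poc_surf = Uncertain(float(np.mean(poc_ml)),
                                  float(np.std(poc_ml, ddof=1)) if len(poc_ml) > 1 else 0.0)
        feat.mld = Uncertain(float(np.mean(mlds)),
                             float(np.std(mlds, ddof=1)) if len(mlds) > 1 else 0.0)
        if not feat.poc_surf.mean > feat.poc_ev:
            diagnostics["skipped_profiles"].append((label, int(i), "esp: clock undefined"))
            continue
        summary = esp_mod.esp_flux(feat, const, seed=rng, n_iter=const.mc_iterations)
        diagnostics["mc_rejections"][f"esp_profile_{i}"] = summary.n_rejected
        feature_rows.append({
            "window": label, "time": feat.time, "z_ev": feat.z_ev,
            "top": feat.top, "bottom": feat.bottom, "poc_ev": feat.poc_ev,
            "aou_anom": feat.aou_anom, "spice_anom": feat.spice_anom,
            "poc_anom": feat.poc_anom, "poc_surf": feat.poc_surf.mean,
            "mld": feat.mld.mean, "flux_median": summary.median,
            "flux_q25": summary.q25, "flux_q75": summary.q75,
            "mc_rejected": summary.n_rejected,
            "unreliable": summary.n_rejected > 0.5 * const.mc_iterations,
        })
        # re-draw to pool per bin (cheap, keeps per-feature summaries intact)
        d_draws = _esp_draws(feat, const, rng)
        draws_by_bin.setdefault(k, []).append(d_draws)
        nobs_by_bin[k] = nobs_by_bin.get(k, 0) + 1

    if draws_by_bin:
        rows = []
        for k in sorted(draws_by_bin):
            pooled = np.concatenate(draws_by_bin[k])
            b0 = anchor + np.timedelta64(int(k * bw * 86400), "s")
            b1 = anchor + np.timedelta64(int((k + 1) * bw * 86400), "s")
            rows.append({"bin_start": b0, "bin_end": b1,
                         "median": float(np.median(pooled)),
                         "q25": float(np.percentile(pooled, 25)),
                         "q75": float(np.percentile(pooled, 75)),
                         "n_obs": nobs_by_bin[k], "pathway": "F_ESP",
                         "window": label})
        flux_frames.append(pd.DataFrame(rows))


def _esp_draws(feat, const, rng):
    n = const.mc_iterations
    poc_surf = rng.normal(feat.poc_surf.mean, feat.poc_surf.sd, n)
    mld = rng.normal(feat.mld.mean, feat.mld.sd, n)
    R = rng.normal(const.respiration.mean, const.respiration.sd, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (feat.z_ev - mld) * R / (poc_surf - feat.poc_ev)
        flux = poc_surf * w
    ok = np.isfinite(flux) & (R > 0) & (poc_surf > feat.poc_ev) & (w > 0)
    return flux[ok]


def _run_photo(derived, comp_chl, idx, const):
    rows = []
    for i in idx:
        d = derived[i]
        alpha = r2 = np.nan
        reason = ""
        if np.isfinite(d.npq_depth):
            npq = photophys.npq_index_profile(d.chl_corrected, d.profile.chl)
            res, info = photophys.alpha_npq_fit(npq, d.ipar, const)
            if res is None:
                reason = info
            else:
                alpha, r2 = res, info
        kd = photophys.kd490(d.z, d.profile.ed[2] if d.profile.ed is not None else np.nan)
        kdp = photophys.kd_par_from_kd490(kd)
        iml = photophys.mixed_layer_light(d.profile.par_sat, kdp, d.mld_bio)
        rows.append({"time": d.time, "alpha_npq": alpha, "r2": r2,
                     "reject_reason": reason, "kd490": kd, "kd_par": kdp,
                     "i_ml": iml, "mld_bio": d.mld_bio,
                     "sun_elevation": d.sun_elevation})
    return pd.DataFrame(rows)
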