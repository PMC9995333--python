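"""Plain-text I/O: missions, ground truth and run reports as CSV/JSON.

Profile files use a long layout (one row per profile and depth) with the
scalar per-profile fields repeated; parking records one row per hourly
sample.  These are the same formats the command-line interface writes and
reads, so a synthetic mission round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParkingSeries, Profile
from .synthetic import Mission, MissionConfig, SyntheticTruth

_PROFILE_VARS = ["T", "S", "chl", "bbp470", "bbp700", "cp660", "o2"]
_ED_COLS = ["ed412", "ed443", "ed490", "ed550"]


def write_mission(mission: Mission, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in mission.profiles:
        frame = {"profile_id": p.profile_id, "time": p.time, "lat": p.lat,
                 "lon": p.lon, "par_sat": p.par_sat, "z": p.z}
        for v in _PROFILE_VARS:
            frame[v] = getattr(p, v) if getattr(p, v) is not None else np.nan
        for j, c in enumerate(_ED_COLS):
            frame[c] = p.ed[j] if p.ed is not None else np.nan
        rows.append(pd.DataFrame(frame))
    pd.concat(rows, ignore_index=True).to_csv(out / "profiles.csv", index=False,
                                              float_format="%.8g")
    park = []
    for s in mission.parkings:
        park.append(pd.DataFrame({
            "phase_id": s.phase_id, "start": s.start, "end": s.end,
            "depth": s.depth, "t_hours": s.t, "atn": s.atn,
        }))
    if park:
        pd.concat(park, ignore_index=True).to_csv(out / "parking.csv", index=False,
                                                  float_format="%.8g")


def read_mission(in_dir: str | Path, o2_gain: float = 1.0) -> Mission:
    """Read a mission; ``o2_gain`` multiplies raw optode oxygen (use the
    air-calibration gain for uncalibrated records, 1.0 for calibrated)."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "profiles.csv", parse_dates=["time"])
    profiles = []
    for pid, g in df.groupby("profile_id", sort=True):
        g = g.sort_values("z")
        ed = np.vstack([g[c].to_numpy(dtype=float) for c in _ED_COLS])
        profiles.append(Profile(
            time=np.datetime64(g["time"].iloc[0]).astype("datetime64[s]"),
            lat=float(g["lat"].iloc[0]), lon=float(g["lon"].iloc[0]),
            z=g["z"].to_numpy(dtype=float),
            T=g["T"].to_numpy(dtype=float), S=g["S"].to_numpy(dtype=float),
            chl=g["chl"].to_numpy(dtype=float),
            bbp470=g["bbp470"].to_numpy(dtype=float),
            bbp700=g["bbp700"].to_numpy(dtype=float),
            cp660=g["cp660"].to_numpy(dtype=float),
            o2=g["o2"].to_numpy(dtype=float) * o2_gain,
            ed=ed, par_sat=float(g["par_sat"].iloc[0]), profile_id=int(pid),
        ))
    parkings = []
    park_path = in_dir / "parking.csv"
    if park_path.exists():
        pk = pd.read_csv(park_path, parse_dates=["start", "end"])
        for pid, g in pk.groupby("phase_id", sort=True):
            g = g.sort_values("t_hours")
            parkings.append(ParkingSeries(
                start=np.datetime64(g["start"].iloc[0]).astype("datetime64[s]"),
                end=np.datetime64(g["end"].iloc[0]).astype("datetime64[s]"),
                t=g["t_hours"].to_numpy(dtype=float),
                atn=g["atn"].to_numpy(dtype=float),
                depth=float(g["depth"].iloc[0]), phase_id=int(pid),
            ))
    return Mission(profiles=profiles, parkings=parkings, config=MissionConfig())


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.mlp_stocks.to_csv(out / "truth_mlp_stocks.csv", index=False)
    truth.trap.to_csv(out / "truth_trap.csv", index=False)
    truth.esp.to_csv(out / "truth_esp.csv", index=False)
    truth.spikes.to_csv(out / "truth_spikes.csv", index=False)
    truth.p_dense.to_csv(out / "truth_stock.csv", index=False)
    scalars = {
        "alpha_npq": truth.alpha_npq,
        "phenology": {k: str(v) for k, v in truth.phenology.items()},
        "times": [str(t) for t in truth.times],
        "mld": truth.mld.tolist(),
        "diameter_um": truth.diameter_um.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(scalars, indent=1))


def write_report(report, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.fluxes.to_csv(out / "fluxes.csv", index=False)
    report.size.to_csv(out / "size.csv", index=False)
    report.esp_features.to_csv(out / "esp_features.csv", index=False)
    report.mlp_events.to_csv(out / "mlp_events.csv", index=False)
    report.ost_phases.to_csv(out / "ost_phases.csv", index=False)
    report.annual_integrals.to_csv(out / "annual_integrals.csv", index=False)
    report.phenology.to_csv(out / "phenology.csv", index=False)
    report.photo.to_csv(out / "photophysiology.csv", index=False)
    summary = {
        "windows": [(lbl, str(a), str(b)) for lbl, a, b in report.windows],
        "annual_integrals": report.annual_integrals.to_dict("records"),
        "n_esp_features": int(len(report.esp_features)),
        "diagnostics": {
            "skipped_profiles": report.diagnostics.get("skipped_profiles", []),
            "missing": report.diagnostics.get("missing", []),
            "mc_rejections": report.diagnostics.get("mc_rejections", {}),
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1, default=str))
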