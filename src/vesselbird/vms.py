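"""Vessel Monitoring System (VMS) track regularization.

Native VMS pings arrive every 1-2 h at arbitrary times.  For the
bird-vessel join they are linearly interpolated onto a shared 10-min UTC
grid, as if all vessels reported simultaneously, and each grid ping is
classified as steaming or fishing by gear-specific speed filters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geo import DomainError, haversine_km, initial_bearing_deg

#: gear -> (lo, hi) fishing-speed band in knots; gears without a band stay unknown
DEFAULT_FISHING_BANDS = {
    "trawl": (1.0, 4.5),
    "purse_seine": (0.0, 2.5),
    "longline": (3.0, 7.0),
}

KM_PER_NM = 1.852


def interpolate_pings(native: pd.DataFrame, grid_step_min: int = 10,
                      max_gap_h: float = 4.0) -> pd.DataFrame:
    """Regularize native pings onto the global ``grid_step_min`` UTC grid.

    Positions are interpolated linearly in lat/lon between bracketing
    native pings; the speed at a grid point is the great-circle length of
    its bracketing native segment divided by the segment duration, and the
    heading is the segment bearing.  Native gaps longer than ``max_gap_h``
    are not interpolated (the track is split there).  Vessels with a single
    ping are skipped with a warning.

    Grid timestamps are aligned to minutes == 0 (mod grid_step_min) of the
    UTC hour, so all vessels share one grid.
    """
    step = pd.Timedelta(minutes=grid_step_min)
    out = []
    for vid, g in native.groupby("vessel_id", sort=True):
        g = g.sort_values("t")
        if len(g) < 2:
            warnings.warn(f"vessel {vid}: single-ping trip skipped")
            continue
        t = pd.DatetimeIndex(g["t"]).asi8 / 1e9  # epoch seconds
        lat, lon = g["lat"].to_numpy(), g["lon"].to_numpy()
        gear = g["gear"].iloc[0]
        t0 = pd.Timestamp(g["t"].iloc[0]).ceil(f"{grid_step_min}min")
        t1 = pd.Timestamp(g["t"].iloc[-1]).floor(f"{grid_step_min}min")
        if t0 > t1:
            continue
        grid = pd.date_range(t0, t1, freq=step)
        gt = grid.asi8 / 1e9
        seg = np.clip(np.searchsorted(t, gt, side="right") - 1, 0, len(t) - 2)
        dt_seg = t[seg + 1] - t[seg]
        frac = np.where(dt_seg > 0, (gt - t[seg]) / np.where(dt_seg > 0, dt_seg, 1.0), 0.0)
        ok = (dt_seg <= max_gap_h * 3600.0) & (frac >= 0.0) & (frac <= 1.0)
        if not ok.any():
            continue
        glat = lat[seg] + frac * (lat[seg + 1] - lat[seg])
        glon = lon[seg] + frac * (lon[seg + 1] - lon[seg])
        seg_km = haversine_km(lat[seg], lon[seg], lat[seg + 1], lon[seg + 1])
        speed_kn = np.where(dt_seg > 0, seg_km / (dt_seg / 3600.0) / KM_PER_NM, 0.0)
        heading = initial_bearing_deg(lat[seg], lon[seg], lat[seg + 1], lon[seg + 1])
        heading = np.where(seg_km > 1e-9, heading, 0.0)
        nat_speed = g["speed_kn"].to_numpy() if "speed_kn" in g.columns else None
        frame = pd.DataFrame({
            "vessel_id": vid, "t": grid[ok], "lat": glat[ok], "lon": glon[ok],
            "speed_kn": speed_kn[ok], "heading_deg": heading[ok],
            "gear": gear, "activity": "unknown",
        })
        if nat_speed is not None:
            # instantaneous speeds reported by the bracketing native pings
            frame["nat_speed_prev_kn"] = nat_speed[seg][ok]
            frame["nat_speed_next_kn"] = nat_speed[seg + 1][ok]
        out.append(frame)
    if not out:
        return pd.DataFrame(columns=["vessel_id", "t", "lat", "lon", "speed_kn",
                                     "heading_deg", "gear", "activity"])
    res = pd.concat(out, ignore_index=True)
    res.attrs["grid_step_min"] = grid_step_min
    return res


def classify_activity(track: pd.DataFrame,
                      fishing_bands: dict | None = None) -> pd.DataFrame:
    """Fill the activity column by gear-specific speed filters.

    fishing iff lo <= speed <= hi for the vessel's gear band, else
    steaming; gears without a configured band become unknown.  When the
    track carries the bracketing native-ping instantaneous speeds
    (``nat_speed_prev_kn``/``nat_speed_next_kn``, as produced by
    ``interpolate_pings``), both must fall inside the band: a grid point
    interpolated across an activity transition is then conservatively
    called steaming, since its position is unreliable.
    """
    if "speed_kn" not in track.columns:
        raise DomainError("track has no speeds")
    bands = DEFAULT_FISHING_BANDS if fishing_bands is None else fishing_bands
    out = track.copy()
    use_native = {"nat_speed_prev_kn", "nat_speed_next_kn"} <= set(out.columns)
    activity = np.full(len(out), "unknown", dtype=object)
    sp = out["speed_kn"].to_numpy()
    for gear, (lo, hi) in bands.items():
        sel = out["gear"].to_numpy() == gear
        in_band = (sp >= lo) & (sp <= hi)
        if use_native:
            # a fast transit hiding entirely inside one native gap leaves
            # both endpoint speeds in the band but inflates the chord
            # speed, so both conditions must hold
            a = out["nat_speed_prev_kn"].to_numpy()
            b = out["nat_speed_next_kn"].to_numpy()
            in_band &= (a >= lo) & (a <= hi) & (b >= lo) & (b <= hi)
        activity[sel] = np.where(in_band[sel], "fishing", "steaming")
    out["activity"] = activity
    return out
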