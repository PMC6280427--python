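"""Foraging-trip segmentation and per-trip movement metrics.

A central-place foraging trip opens when a bird's GPS track leaves the
colony departure radius and closes at the first fix back inside.  Boundary
fixes (last inside before departure, first inside after return) are
included so length integrals start and end at the colony.  Trips of at
most 3 days are "short"; the analysis stratum for the group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import Colony, DomainError, haversine_km

SHORT_TRIP_MAX_DAYS = 3.0
MIN_AT_SEA_FIXES = 3


def colony_distance_km(fixes: pd.DataFrame, colony: Colony) -> np.ndarray:
    return haversine_km(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(),
                        colony.pos.lat, colony.pos.lon)


def segment_trips(track: pd.DataFrame, colony: Colony) -> pd.DataFrame:
    """Segment one or more birds' fixes into complete foraging trips.

    Returns the input fixes annotated with a ``trip_id`` column (NaN at the
    colony); a trip is complete when both boundary fixes inside the radius
    are observed, and is kept only with >= 3 at-sea fixes.
    """
    out = []
    for bird_id, g in track.groupby("bird_id", sort=True):
        g = g.sort_values("t").reset_index(drop=True)
        if g["t"].duplicated().any() or not g["t"].is_monotonic_increasing:
            raise DomainError(f"bird {bird_id}: fixes not strictly increasing in time")
        inside = colony_distance_km(g, colony) <= colony.departure_radius_km
        trip_id = np.full(len(g), None, dtype=object)
        n_trip = 0
        i = 0
        while i < len(g) - 1:
            if inside[i] and not inside[i + 1]:
                # departure boundary at i; find return boundary
                j = i + 1
                while j < len(g) and not inside[j]:
                    j += 1
                if j < len(g):  # complete trip i..j inclusive
                    if j - i - 1 >= MIN_AT_SEA_FIXES:
                        n_trip += 1
                        trip_id[i:j + 1] = f"{bird_id}_T{n_trip:02d}"
                    i = j
                    continue
                else:
                    break
            i += 1
        g = g.copy()
        g["trip_id"] = trip_id
        out.append(g)
    return pd.concat(out, ignore_index=True) if out else track.assign(trip_id=None)


def trip_table(fixes_with_trips: pd.DataFrame, colony: Colony,
               events=None) -> pd.DataFrame:
    """One row per complete trip with duration, category and metrics.

    ``events`` is an optional list of interaction events (objects with
    bird_id and fix_times) counted into each trip they fall inside.
    """
    rows = []
    sel = fixes_with_trips[fixes_with_trips["trip_id"].notna()]
    for tid, g in sel.groupby("trip_id", sort=True):
        g = g.sort_values("t")
        m = compute_trip_metrics(g, colony, events)
        start, end = g["t"].iloc[0], g["t"].iloc[-1]
        dur = (end - start).total_seconds() / 86400.0
        rows.append({
            "bird_id": g["bird_id"].iloc[0], "trip_id": tid,
            "start": start, "end": end, "duration_days": dur,
            "category": "short" if dur <= SHORT_TRIP_MAX_DAYS else "long",
            **m,
        })
    cols = ["bird_id", "trip_id", "start", "end", "duration_days", "category",
            "trip_length_km", "max_colony_distance_km", "n_interactions", "int_flag"]
    return pd.DataFrame(rows, columns=cols)


def compute_trip_metrics(trip_fixes: pd.DataFrame, colony: Colony,
                         events=None) -> dict:
    """trip_length_km (summed consecutive haversine), max distance from the
    colony, and the count of interaction events inside the trip."""
    if len(trip_fixes) == 0:
        raise DomainError("empty trip")
    g = trip_fixes.sort_values("t")
    lat, lon = g["lat"].to_numpy(), g["lon"].to_numpy()
    length = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))) \
        if len(g) > 1 else 0.0
    max_d = float(np.max(colony_distance_km(g, colony)))
    n_int = 0
    if events is not None:
        t0, t1 = g["t"].iloc[0], g["t"].iloc[-1]
        bird = g["bird_id"].iloc[0]
        for ev in events:
            if ev.bird_id == bird and t0 <= pd.Timestamp(ev.fix_times[0]) <= t1:
                n_int += 1
    return {
        "trip_length_km": length,
        "max_colony_distance_km": max_d,
        "n_interactions": n_int,
        "int_flag": "INT_YES" if n_int >= 1 else "INT_NO",
    }


def write_trip_table(trips: pd.DataFrame, path) -> None:
    out = trips.copy()
    for c in ("start", "end"):
        out[c] = pd.DatetimeIndex(out[c]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
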