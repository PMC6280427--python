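"""Shared geographic and temporal primitives.

All positions are WGS84 decimal degrees; all distances spherical
great-circle kilometres (R = 6371 km).  Timestamps are handled internally
as timezone-naive UTC; the fixed local offset (UTC+2, no DST) is applied
only for diel summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
LOCAL_UTC_OFFSET_H = 2

#: Linosa Island colony, 35d51'33"N 12d51'34"E
COLONY_LAT = 35.0 + 51.0 / 60 + 33.0 / 3600
COLONY_LON = 12.0 + 51.0 / 60 + 34.0 / 3600

BIRD_GPS_COLUMNS = ["bird_id", "timestamp_iso8601", "lat", "lon"]
VESSEL_PING_COLUMNS = [
    "vessel_id", "timestamp_iso8601", "lat", "lon",
    "speed_kn", "heading_deg", "gear", "activity",
]

GEAR_TYPES = ("trawl", "purse_seine", "longline", "other")
ACTIVITY_TYPES = ("steaming", "fishing", "unknown")


class DomainError(ValueError):
    """Invalid domain input (coordinates out of range, misaligned series...)."""


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float

    def __post_init__(self):
        _check_coords(self.lat, self.lon)


@dataclass(frozen=True)
class Colony:
    """Breeding colony: position plus the radius delimiting trip start/end."""

    pos: GeoPoint
    departure_radius_km: float = 2.0

    def __post_init__(self):
        if self.departure_radius_km <= 0:
            raise DomainError("departure_radius_km must be positive")


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise DomainError("non-finite coordinates")
    if np.any(np.abs(lat) > 90.0):
        raise DomainError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise DomainError("longitude outside [-180, 180]")


LINOSA = Colony(GeoPoint(COLONY_LAT, COLONY_LON))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between two points (vectorised).

    Spherical Earth with R = 6371.0 km; symmetric and non-negative.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def to_local_time(t):
    """UTC -> fixed UTC+2 local time (no DST logic)."""
    return t + pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)


def from_local_time(t):
    """Fixed UTC+2 local time -> UTC."""
    return t - pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)


# ---------------------------------------------------------------------------
# Solar position (NOAA general solar equations)
# ---------------------------------------------------------------------------

def _solar_coefficients(times_utc: pd.DatetimeIndex):
    """Fractional-year Fourier series for equation of time (min) and solar
    declination (rad), from the NOAA general solar position calculations."""
    doy = times_utc.dayofyear.to_numpy()
    hour = (times_utc.hour + times_utc.minute / 60.0 + times_utc.second / 3600.0).to_numpy()
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    return eqtime, decl


def sun_events_utc(date, lat: float, lon: float):
    """(sunrise, sunset) as UTC timestamps for the given calendar date.

    Standard refraction-corrected horizon (zenith 90.833 deg).  Raises
    DomainError for polar day/night, which cannot occur at the study
    latitude in summer.
    """
    _check_coords(lat, lon)
    date = pd.Timestamp(date).normalize()
    noon_guess = date + pd.Timedelta(hours=12) - pd.Timedelta(hours=lon / 15.0)
    eqtime, decl = _solar_coefficients(pd.DatetimeIndex([noon_guess]))
    eqtime, decl = eqtime[0], decl[0]
    phi = np.radians(lat)
    zenith = np.radians(90.833)
    cos_ha = np.cos(zenith) / (np.cos(phi) * np.cos(decl)) - np.tan(phi) * np.tan(decl)
    if not -1.0 < cos_ha < 1.0:
        raise DomainError("polar day/night: sun does not cross the horizon")
    ha = np.degrees(np.arccos(cos_ha))  # half day-length in degrees
    sunrise_min = 720.0 - 4.0 * (lon + ha) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha) - eqtime
    return (date + pd.Timedelta(minutes=sunrise_min),
            date + pd.Timedelta(minutes=sunset_min))


def night_mask(times_local, lat: float = COLONY_LAT, lon: float = COLONY_LON):
    """True where a local (UTC+2) timestamp falls between sunset and sunrise.

    Night is evaluated against the sunrise/sunset of each timestamp's own
    local calendar date: before that date's sunrise or after its sunset.
    """
    times_local = pd.DatetimeIndex(pd.to_datetime(times_local))
    out = np.zeros(len(times_local), dtype=bool)
    times_utc = from_local_time(times_local)
    for date in np.unique(times_local.normalize()):
        sel = times_local.normalize() == date
        # sun events of the local calendar date (same nominal UTC date)
        rise, set_ = sun_events_utc(pd.Timestamp(date), lat, lon)
        t = times_utc[sel]
        out[sel] = (t < rise) | (t > set_)
    return out


# ---------------------------------------------------------------------------
# CSV / GeoJSON interfaces
# ---------------------------------------------------------------------------

def read_bird_gps(path) -> pd.DataFrame:
    """Read bird GPS fixes: columns bird_id, timestamp_iso8601, lat, lon.

    Returns a DataFrame with columns [bird_id, t, lat, lon], time-sorted
    per bird; duplicate timestamps within a bird raise DomainError.
    """
    df = pd.read_csv(path)
    missing = set(BIRD_GPS_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"bird GPS file missing columns: {sorted(missing)}")
    df = df.rename(columns={"timestamp_iso8601": "t"})
    df["t"] = pd.to_datetime(df["t"])
    _check_coords(df["lat"].to_numpy(), df["lon"].to_numpy())
    df = df.sort_values(["bird_id", "t"], kind="stable").reset_index(drop=True)
    if df.duplicated(["bird_id", "t"]).any():
        raise DomainError("duplicate (bird_id, timestamp) fixes")
    return df[["bird_id", "t", "lat", "lon"]]


def write_bird_gps(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"t": "timestamp_iso8601"}).copy()
    out["timestamp_iso8601"] = pd.DatetimeIndex(out["timestamp_iso8601"]).strftime(
        "%Y-%m-%dT%H:%M:%S")
    out[BIRD_GPS_COLUMNS].to_csv(path, index=False)


def read_vessel_pings(path) -> pd.DataFrame:
    """Read vessel pings in the shared CSV dialect.

    Returns [vessel_id, t, lat, lon, speed_kn, heading_deg, gear, activity].
    """
    df = pd.read_csv(path)
    missing = set(VESSEL_PING_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"vessel ping file missing columns: {sorted(missing)}")
    df = df.rename(columns={"timestamp_iso8601": "t"})
    df["t"] = pd.to_datetime(df["t"])
    _check_coords(df["lat"].to_numpy(), df["lon"].to_numpy())
    if (df["speed_kn"] < 0).any():
        raise DomainError("negative vessel speed")
    if ((df["heading_deg"] < 0) | (df["heading_deg"] >= 360)).any():
        raise DomainError("heading outside [0, 360)")
    return df.sort_values(["vessel_id", "t"], kind="stable").reset_index(drop=True)


def write_vessel_pings(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"t": "timestamp_iso8601"}).copy()
    out["timestamp_iso8601"] = pd.DatetimeIndex(out["timestamp_iso8601"]).strftime(
        "%Y-%m-%dT%H:%M:%S")
    out[VESSEL_PING_COLUMNS].to_csv(path, index=False)


def tracks_to_geojson(df: pd.DataFrame, id_col: str, path=None) -> dict:
    """Export one LineString feature per track id (lon, lat order)."""
    features = []
    for tid, g in df.groupby(id_col, sort=True):
        coords = [[float(lo), float(la)] for lo, la in zip(g["lon"], g["lat"])]
        features.append({
            "type": "Feature",
            "properties": {id_col: str(tid), "n_fixes": len(g)},
            "geometry": {"type": "LineString", "coordinates": coords},
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
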