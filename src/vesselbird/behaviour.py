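"""Accelerometer-based behaviour classification.

Converts 25 Hz tri-axial acceleration into a VeDBA (Vectorial Dynamic Body
Acceleration) series, a per-second ethogram with four exhaustive labels --
SIT (sitting on the water), FLAP (flapping flight), GLIDE (gliding flight)
and OTHER -- and daily activity summaries.

The ethogram follows the standard biologging recipe for shearwater-like
flap-gliders: the static (gravitational) component of each axis is a 1-s
centred running mean, VeDBA is the Euclidean norm of the dynamic residuals,
sitting on the water is VeDBA within 0.1-1.0 g at low ground speed,
flapping is found by two-cluster k-means on windowed amplitude spectra of
|Z| (the cluster with the higher wingbeat-band peak), and gliding fills
short gaps between flapping bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from sklearn.cluster import KMeans

from .geo import DomainError, to_local_time

SIT, FLAP, GLIDE, OTHER = "SIT", "FLAP", "GLIDE", "OTHER"
LABELS = (SIT, FLAP, GLIDE, OTHER)

#: integer codes used in per-second label arrays
LABEL_CODES = {SIT: 0, FLAP: 1, GLIDE: 2, OTHER: 3}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class AccelSeries:
    """Fixed-rate tri-axial acceleration stream of one bird.

    Axes follow device orientation: X head-tail, Y right-left,
    Z dorso-ventral; units of g.
    """

    bird_id: str
    t0: pd.Timestamp
    rate_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise DomainError("axis arrays must have equal length")
        if self.rate_hz <= 0:
            raise DomainError("rate_hz must be positive")
        for a in (self.ax, self.ay, self.az):
            if np.any(np.abs(a) >= 16.0):
                raise DomainError("acceleration outside +/-16 g device range")
        self.t0 = pd.Timestamp(self.t0)

    def __len__(self):
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz


@dataclass
class VedbaSeries:
    bird_id: str
    t0: pd.Timestamp
    rate_hz: float
    vedba: np.ndarray            # per sample, g
    per_second: np.ndarray       # per-second means, g

    def __post_init__(self):
        if np.any(self.vedba < 0) or np.any(self.per_second < 0):
            raise DomainError("VeDBA must be non-negative")


def vedba_norm(dx, dy, dz):
    """VeDBA(g) = sqrt(ax^2 + ay^2 + az^2) of the dynamic components."""
    dx, dy, dz = (np.asarray(a, dtype=float) for a in (dx, dy, dz))
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def estimate_static(a: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    """Static (gravitational) component: centred running mean over window_s."""
    size = max(2, int(round(window_s * rate_hz)))
    return uniform_filter1d(np.asarray(a, dtype=float), size=size, mode="nearest")


def per_second_means(x: np.ndarray, rate_hz: float) -> np.ndarray:
    n_sec = int(np.ceil(len(x) / rate_hz))
    sec_idx = (np.arange(len(x)) / rate_hz).astype(int)
    sums = np.bincount(sec_idx, weights=x, minlength=n_sec)
    counts = np.bincount(sec_idx, minlength=n_sec)
    return sums / np.maximum(counts, 1)


def compute_vedba(acc: AccelSeries, static_window_s: float = 1.0,
                  smooth_output: bool = False) -> VedbaSeries:
    """VeDBA of an acceleration stream.

    The static component of each axis is removed by a centred running mean
    over ``static_window_s``; the per-sample VeDBA is the norm of the three
    dynamic residuals.  ``smooth_output=True`` additionally applies the same
    running mean to the VeDBA series itself (alternative reading of
    "1 s smoothing").
    """
    if static_window_s < 2.0 / acc.rate_hz:
        raise DomainError("static_window_s shorter than two samples")
    if acc.duration_s < static_window_s:
        raise DomainError("series shorter than the static window")
    dyn = [a - estimate_static(a, acc.rate_hz, static_window_s)
           for a in (acc.ax, acc.ay, acc.az)]
    v = vedba_norm(*dyn)
    if smooth_output:
        v = uniform_filter1d(v, size=max(2, int(round(static_window_s * acc.rate_hz))),
                             mode="nearest")
    return VedbaSeries(acc.bird_id, acc.t0, acc.rate_hz, v,
                       per_second_means(v, acc.rate_hz))


def classify_sitting(per_second_vedba: np.ndarray, speed_ms: np.ndarray,
                     vedba_lo: float = 0.1, vedba_hi: float = 1.0,
                     speed_max: float = 2.0) -> np.ndarray:
    """Per-second sitting-on-the-water flags.

    SIT iff vedba_lo <= mean VeDBA <= vedba_hi and ground speed <= speed_max.
    """
    per_second_vedba = np.asarray(per_second_vedba, dtype=float)
    speed_ms = np.asarray(speed_ms, dtype=float)
    if per_second_vedba.shape != speed_ms.shape:
        raise DomainError("VeDBA and speed series are misaligned")
    return ((per_second_vedba >= vedba_lo) & (per_second_vedba <= vedba_hi)
            & (speed_ms <= speed_max))


def _window_spectra(abs_z: np.ndarray, rate_hz: float, window_s: float):
    """Amplitude spectra of |Z| in contiguous non-overlapping windows."""
    n_win_samples = int(round(window_s * rate_hz))
    n_win = len(abs_z) // n_win_samples
    if n_win == 0:
        raise DomainError("stream shorter than one spectral window")
    segs = abs_z[: n_win * n_win_samples].reshape(n_win, n_win_samples)
    segs = segs - segs.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(segs, axis=1)) * 2.0 / n_win_samples
    freqs = np.fft.rfftfreq(n_win_samples, d=1.0 / rate_hz)
    return amp[:, 1:], freqs[1:]  # drop DC


def detect_flapping(acc: AccelSeries, window_s: float = 1.0,
                    band_hz: tuple = (2.0, 8.0), seed: int = 0,
                    tie_tol: float = 0.10, min_peak_g: float = 0.2) -> np.ndarray:
    """Per-window flapping flags from two-cluster spectral analysis of |Z|.

    Windows are partitioned by k-means (k=2, 10 restarts, fixed seed) on
    their amplitude spectra; the cluster whose mean peak amplitude inside
    ``band_hz`` is higher is flapping.  Two degenerate cases yield no
    flapping at all: the cluster peaks differ by less than ``tie_tol``
    (relative), or the winning cluster's peak stays below ``min_peak_g``
    (wingbeats carry ~1 g of dynamic acceleration, an order of magnitude
    above sensor noise or wave-induced motion, so a flightless stream must
    not acquire flapping labels just because k-means always splits).
    """
    if acc.duration_s < 10.0:
        raise DomainError("need at least 10 s of data for spectral clustering")
    amp, freqs = _window_spectra(np.abs(acc.az), acc.rate_hz, window_s)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if amp.std() < 1e-12:  # all-constant signal: single degenerate cluster
        return np.zeros(len(amp), dtype=bool)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    lab = km.fit_predict(amp)
    peaks = np.array([amp[lab == k][:, band].max(axis=1).mean() if np.any(lab == k)
                      else 0.0 for k in (0, 1)])
    hi, lo = peaks.max(), peaks.min()
    if hi < min_peak_g or (hi - lo) / hi < tie_tol:
        return np.zeros(len(amp), dtype=bool)
    return lab == int(np.argmax(peaks))


def infer_gliding(flap_flags: np.ndarray, window_s: float = 1.0,
                  max_gap_s: float = 30.0) -> np.ndarray:
    """GLIDE flags: non-flapping runs bounded on both sides by flapping and
    shorter than ``max_gap_s``.  Leading/trailing non-flap time is never
    gliding."""
    flap = np.asarray(flap_flags, dtype=bool)
    glide = np.zeros_like(flap)
    idx = np.flatnonzero(flap)
    if len(idx) < 2:
        return glide
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap > 0 and gap * window_s < max_gap_s:
            glide[a + 1:b] = True
    return glide


def build_ethogram(acc: AccelSeries, speed_ms: np.ndarray | None = None,
                   static_window_s: float = 1.0, window_s: float = 1.0,
                   band_hz: tuple = (2.0, 8.0), max_gap_s: float = 30.0,
                   vedba_lo: float = 0.1, vedba_hi: float = 1.0,
                   speed_max: float = 2.0, seed: int = 0):
    """Full per-second ethogram of one stream.

    Label priority: FLAP (spectral cluster), then GLIDE (bounded gaps),
    then SIT (VeDBA band + speed), else OTHER.  Returns
    ``(labels, vedba_series)`` where labels is a per-second array of
    label strings covering the recorded time.
    """
    v = compute_vedba(acc, static_window_s=static_window_s)
    n_sec = len(v.per_second)
    if speed_ms is None:
        speed_ms = np.zeros(n_sec)
    flap_w = detect_flapping(acc, window_s=window_s, band_hz=band_hz, seed=seed)
    glide_w = infer_gliding(flap_w, window_s=window_s, max_gap_s=max_gap_s)
    # per-window flags onto the per-second grid (window_s defaults to 1 s)
    sec_of_win = (np.arange(len(flap_w)) * window_s).astype(int)
    flap_s = np.zeros(n_sec, dtype=bool)
    glide_s = np.zeros(n_sec, dtype=bool)
    flap_s[sec_of_win[flap_w]] = True
    glide_s[sec_of_win[glide_w]] = True
    sit_s = classify_sitting(v.per_second, np.asarray(speed_ms)[:n_sec],
                             vedba_lo, vedba_hi, speed_max)
    labels = np.full(n_sec, OTHER, dtype=object)
    labels[sit_s] = SIT
    labels[glide_s & ~flap_s] = GLIDE
    labels[flap_s] = FLAP
    return labels, v


def segments_from_labels(labels: np.ndarray, t0, bird_id: str) -> pd.DataFrame:
    """Collapse a per-second label array into contiguous EthogramSegments."""
    labels = np.asarray(labels, dtype=object)
    t0 = pd.Timestamp(t0)
    if len(labels) == 0:
        return pd.DataFrame(columns=["bird_id", "start", "end", "label"])
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return pd.DataFrame({
        "bird_id": bird_id,
        "start": [t0 + pd.Timedelta(seconds=int(s)) for s in starts],
        "end": [t0 + pd.Timedelta(seconds=int(e)) for e in ends],
        "label": labels[starts],
    })


def write_ethogram(segments: pd.DataFrame, path) -> None:
    out = segments.copy()
    for c in ("start", "end"):
        out[c] = pd.DatetimeIndex(out[c]).strftime("%Y-%m-%dT%H:%M:%S")
    out[["bird_id", "start", "end", "label"]].to_csv(path, index=False)


def read_accel_csv(path, bird_id: str = "bird") -> AccelSeries:
    """Read a long-format accelerometer CSV
    (timestamp_iso8601, ax_g, ay_g, az_g); the rate is inferred from the
    first two timestamps."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["timestamp_iso8601"])
    if len(df) < 2:
        raise DomainError("accelerometer stream needs >= 2 samples")
    dt = (t.iloc[1] - t.iloc[0]).total_seconds()
    if dt <= 0:
        raise DomainError("non-increasing accelerometer timestamps")
    return AccelSeries(bird_id, t.iloc[0], 1.0 / dt,
                       df["ax_g"].to_numpy(), df["ay_g"].to_numpy(),
                       df["az_g"].to_numpy())


def read_ethogram(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c])
    return df


def labels_from_segments(segments: pd.DataFrame) -> dict:
    """Expand an ethogram segment table back into per-second label arrays:
    bird_id -> (t0, labels)."""
    out = {}
    for bid, g in segments.groupby("bird_id"):
        t0 = g["start"].min()
        n = int((g["end"].max() - t0).total_seconds())
        lab = np.full(n, OTHER, dtype=object)
        for _, row in g.iterrows():
            s = int((row["start"] - t0).total_seconds())
            e = int((row["end"] - t0).total_seconds())
            lab[s:e] = row["label"]
        out[bid] = (t0, lab)
    return out


def daily_summaries(labels: np.ndarray, vedba: VedbaSeries,
                    interval_min: int = 5) -> pd.DataFrame:
    """Per local (UTC+2) calendar day: flight hours and daily VeDBA sum.

    Daily flight time is the summed duration of FLAP and GLIDE seconds, in
    hours.  The daily sum of VeDBA is the sum over the day's ``interval_min``
    intervals of the interval mean of per-second VeDBA (the per-5-min-mean
    summation convention; magnitudes are comparable only internally).
    """
    labels = np.asarray(labels, dtype=object)
    n_sec = len(vedba.per_second)
    if len(labels) < n_sec:
        raise DomainError("ethogram does not cover the VeDBA time span")
    sec_times = to_local_time(pd.date_range(vedba.t0, periods=n_sec, freq="1s"))
    days = sec_times.normalize()
    interval = sec_times.floor(f"{interval_min}min")
    df = pd.DataFrame({
        "day": days, "interval": interval,
        "vedba": vedba.per_second,
        "flight": np.isin(labels[:n_sec], [FLAP, GLIDE]),
    })
    per_int = df.groupby(["day", "interval"], sort=True).agg(
        vedba_mean=("vedba", "mean"))
    per_day_vedba = per_int.groupby("day")["vedba_mean"].sum()
    per_day_flight = df.groupby("day")["flight"].sum() / 3600.0
    out = pd.DataFrame({
        "bird_id": vedba.bird_id,
        "date": per_day_vedba.index,
        "daily_vedba_sum": per_day_vedba.to_numpy(),
        "daily_flight_time_h": per_day_flight.reindex(per_day_vedba.index).to_numpy(),
    }).reset_index(drop=True)
    if (out["daily_flight_time_h"] > 24).any():
        raise DomainError("daily flight time exceeds 24 h")
    return out


def ground_speed_per_second(gps: pd.DataFrame, t0, n_seconds: int) -> np.ndarray:
    """Per-second ground speed (m/s) from 5-min GPS fixes of one bird.

    Every second inside a GPS segment gets that segment's mean speed
    (haversine distance / elapsed time): the speed a fix interval actually
    certifies.  Interpolating between segment midpoints instead would
    bleed flight speed into adjacent resting intervals and veto genuine
    sitting near behaviour transitions.  Outside the GPS span the speed
    is 0.
    """
    from .geo import haversine_km
    if len(gps) < 2:
        return np.zeros(n_seconds)
    g = gps.sort_values("t")
    t = (pd.DatetimeIndex(g["t"]) - pd.Timestamp(t0)).total_seconds().to_numpy()
    d_km = haversine_km(g["lat"].to_numpy()[:-1], g["lon"].to_numpy()[:-1],
                        g["lat"].to_numpy()[1:], g["lon"].to_numpy()[1:])
    dt = np.diff(t)
    speed = d_km * 1000.0 / np.maximum(dt, 1e-9)
    sec = np.arange(n_seconds, dtype=float)
    seg = np.clip(np.searchsorted(t, sec, side="right") - 1, 0, len(speed) - 1)
    out = speed[seg]
    out[(sec < t[0]) | (sec >= t[-1])] = 0.0
    return out
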