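"""Bird-vessel interaction detection.

Two-step procedure:

1. **Approach events.**  Each bird GPS fix is joined with the single grid
   ping of every vessel inside a half-open +/-5-min window and a 50-km
   radius.  Maximal runs of >= 2 consecutive fixes whose distance to one
   vessel strictly decreases, with a cumulative decrease of >= 500 m and
   starting within the 30-km maximum attraction distance, are approach
   events.

2. **Interaction distance.**  Pooled bird-vessel pairs are binned by
   distance (0.25-km bins); each bin's mean percentage of sitting-on-water
   behaviour forms a distance profile.  A continuous two-segment linear
   model is fitted by profiling the breakpoint on a fine grid; the
   breakpoint is the interaction distance, with a 95% bootstrap CI over
   bins.  Approach events whose minimum distance reaches inside the
   interaction distance are validated as interaction events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import SIT
from .geo import DomainError, haversine_km, night_mask, to_local_time


class ProfileError(ValueError):
    """Distance profile unusable for fitting (too few retained bins)."""


class DegenerateFitError(ValueError):
    """Breakpoint RSS profile is flat; no identifiable breakpoint."""


@dataclass
class ApproachEvent:
    """A run of bird fixes converging on one vessel."""

    bird_id: str
    vessel_id: str
    fix_times: list
    distances_km: list
    validated: bool = False
    activities: list | None = None   # vessel activity at each paired ping

    def __post_init__(self):
        if len(self.fix_times) < 2:
            raise DomainError("approach event needs >= 2 fixes")
        d = np.asarray(self.distances_km, dtype=float)
        if not np.all(np.diff(d) < 0):
            raise DomainError("approach distances must be strictly decreasing")

    @property
    def start_distance_km(self) -> float:
        return float(self.distances_km[0])

    @property
    def min_distance_km(self) -> float:
        return float(self.distances_km[-1])


@dataclass
class DistanceProfile:
    """Binned mean sitting percentage vs distance from a vessel."""

    bin_lo_km: np.ndarray
    bin_hi_km: np.ndarray
    mean_sit_pct: np.ndarray
    counts: np.ndarray
    bin_km: float

    @property
    def centers_km(self) -> np.ndarray:
        return (self.bin_lo_km + self.bin_hi_km) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_km": self.bin_lo_km, "bin_hi_km": self.bin_hi_km,
            "n_pairs": self.counts, "mean_sit_pct": self.mean_sit_pct,
        })


@dataclass
class BreakpointFit:
    """Two-segment continuous linear fit; the breakpoint is the interaction
    distance."""

    breakpoint_km: float
    ci95: tuple
    slopes: tuple          # (left, right) in %/km
    intercept: float       # % at distance 0
    rss: float
    n_bins: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slopes[0] * x
                + (self.slopes[1] - self.slopes[0])
                * np.maximum(0.0, x - self.breakpoint_km))


# ---------------------------------------------------------------------------
# Step 1: the spatio-temporal join and the approach rule
# ---------------------------------------------------------------------------

def match_pairs(fixes: pd.DataFrame, vessel_grid: pd.DataFrame,
                window_min: float = 5.0, radius_km: float = 50.0,
                grid_step_min: int = 10,
                fishing_only: bool = False) -> pd.DataFrame:
    """Join bird fixes with the unique vessel grid ping in [t-w, t+w).

    With a 10-min vessel grid and a 5-min half-window the half-open window
    contains exactly one grid instant, so one single ping per vessel is
    associated with each bird position.  Pairs farther than ``radius_km``
    are dropped.  With ``fishing_only=True`` only grid pings classified as
    fishing enter the join: interpolated steaming positions carry multi-km
    displacement (long fast legs between sparse native pings), while
    fishing hauls are slow and quasi-linear, so fishing pings are the ones
    whose bird-vessel distances are trustworthy at the sub-km scale.
    Returns columns [bird_id, t, vessel_id, grid_t, distance_km].
    """
    if fishing_only and "activity" in vessel_grid.columns:
        vessel_grid = vessel_grid[vessel_grid["activity"] == "fishing"]
    if len(fixes) == 0 or len(vessel_grid) == 0:
        return pd.DataFrame(columns=["bird_id", "t", "vessel_id", "grid_t",
                                     "distance_km"])
    step = pd.Timedelta(minutes=grid_step_min)
    w = pd.Timedelta(minutes=window_min)
    f = fixes.copy()
    # unique grid instant in the half-open window [t-w, t+w)
    f["grid_t"] = (pd.DatetimeIndex(f["t"]) - w).ceil(step)
    valid = f["grid_t"] < pd.DatetimeIndex(f["t"]) + w
    f = f[valid]
    merged = f.merge(
        vessel_grid.rename(columns={"t": "grid_t", "lat": "v_lat", "lon": "v_lon"}),
        on="grid_t", how="inner", suffixes=("", "_v"))
    if len(merged) == 0:
        return pd.DataFrame(columns=["bird_id", "t", "vessel_id", "grid_t",
                                     "distance_km"])
    merged["distance_km"] = haversine_km(
        merged["lat"].to_numpy(), merged["lon"].to_numpy(),
        merged["v_lat"].to_numpy(), merged["v_lon"].to_numpy())
    merged = merged[merged["distance_km"] <= radius_km]
    cols = ["bird_id", "t", "vessel_id", "grid_t", "distance_km"]
    if "activity" in merged.columns:
        cols.append("activity")
    return (merged[cols]
            .sort_values(["bird_id", "vessel_id", "t"]).reset_index(drop=True))


def attach_sit_fraction(pairs: pd.DataFrame, labels_by_bird: dict,
                        interval_s: int = 300) -> pd.DataFrame:
    """Attach the SIT fraction of each fix's forward 5-min interval.

    ``labels_by_bird`` maps bird_id -> (t0, per-second label array).
    Seconds outside the labelled span contribute nothing; fixes with no
    labelled second get NaN.
    """
    out = pairs.copy()
    frac = np.full(len(out), np.nan)
    for bird, (t0, labels) in labels_by_bird.items():
        sel = np.flatnonzero((out["bird_id"] == bird).to_numpy())
        if len(sel) == 0:
            continue
        t0 = pd.Timestamp(t0)
        sit = np.asarray(labels, dtype=object) == SIT
        csum = np.concatenate([[0], np.cumsum(sit)])
        start = ((pd.DatetimeIndex(out["t"].iloc[sel]) - t0)
                 .total_seconds().to_numpy().astype(np.int64))
        lo = np.clip(start, 0, len(sit))
        hi = np.clip(start + interval_s, 0, len(sit))
        n = hi - lo
        with np.errstate(invalid="ignore"):
            frac[sel] = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1),
                                 np.nan)
    out["sit_fraction"] = frac
    return out


def detect_approaches(pairs: pd.DataFrame, min_drop_km: float = 0.5,
                      max_start_km: float = 30.0, gps_step_min: float = 5.0,
                      per_step_drop: bool = False) -> list:
    """Approach events: maximal strictly-decreasing distance runs.

    A run must consist of temporally consecutive bird fixes (spacing one
    nominal GPS step, with 50% tolerance), have >= 2 fixes, start within
    ``max_start_km`` (runs beginning farther out are trimmed to the first
    fix inside) and decrease cumulatively by >= ``min_drop_km``.  With
    ``per_step_drop=True`` every single step must decrease by
    >= ``min_drop_km`` instead (alternative reading of the rule).
    Output order is (bird_id, vessel_id, start time) and is invariant to
    the input ordering of unrelated vessels.
    """
    events = []
    if len(pairs) == 0:
        return events
    max_step = pd.Timedelta(minutes=gps_step_min * 1.5)
    for (bird, vessel), g in pairs.groupby(["bird_id", "vessel_id"], sort=True):
        g = g.sort_values("t")
        t = pd.DatetimeIndex(g["t"])
        d = g["distance_km"].to_numpy()
        act = g["activity"].to_numpy() if "activity" in g.columns else None
        # break at temporal gaps or non-decreasing steps
        consec = (np.diff(t.asi8) <= max_step.value) & (np.diff(d) < 0)
        run_start = 0
        for i in range(len(d)):
            end_run = i == len(d) - 1 or not consec[i]
            if end_run:
                ev = _make_event(bird, vessel, t[run_start:i + 1], d[run_start:i + 1],
                                 None if act is None else act[run_start:i + 1],
                                 min_drop_km, max_start_km, per_step_drop)
                if ev is not None:
                    events.append(ev)
                run_start = i + 1
    return events


def _make_event(bird, vessel, t, d, act, min_drop_km, max_start_km,
                per_step_drop):
    # trim to the first fix within the attraction distance
    inside = np.flatnonzero(d <= max_start_km)
    if len(inside) == 0:
        return None
    t, d = t[inside[0]:], d[inside[0]:]
    act = None if act is None else act[inside[0]:]
    if len(d) < 2:
        return None
    if per_step_drop:
        if np.any(-np.diff(d) < min_drop_km):
            return None
    elif d[0] - d[-1] < min_drop_km:
        return None
    return ApproachEvent(bird, vessel, list(t), list(d),
                         activities=None if act is None else list(act))


# ---------------------------------------------------------------------------
# Step 2: distance profile and breakpoint (the interaction distance)
# ---------------------------------------------------------------------------

def select_profile_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """The trustworthy pair subset for the sitting-vs-distance profile:
    fishing-classified pings, simultaneous fix/grid instants, and each
    fix's nearest vessel (the vessel the behaviour responds to)."""
    pp = pairs
    if "activity" in pp.columns:
        pp = pp[pp["activity"] == "fishing"]
    if "grid_t" in pp.columns:
        pp = pp[pp["grid_t"] == pp["t"]]
    if len(pp):
        pp = pp.loc[pp.groupby(["bird_id", "t"])["distance_km"].idxmin()]
    return pp


def build_distance_profile(pairs: pd.DataFrame, bin_km: float = 0.25,
                           min_count: int = 110, max_km: float = 30.0,
                           scale_ref: int = 4500) -> DistanceProfile:
    """Bin pairs by distance and average their sitting percentage.

    Bins are contiguous half-open [lo, lo+bin_km) intervals from 0 to
    ``max_km``.  Bins with fewer than the effective minimum count are
    dropped; the minimum scales down proportionally (x N_pairs/scale_ref)
    when fewer than ``scale_ref`` pairs are pooled, floored at 5.
    """
    p = pairs.dropna(subset=["sit_fraction"])
    p = p[p["distance_km"] < max_km]
    n_pairs = len(p)
    eff_min = max(5, int(np.ceil(min_count * min(1.0, n_pairs / scale_ref))))
    edges = np.arange(0.0, max_km + bin_km / 2, bin_km)
    idx = np.floor(p["distance_km"].to_numpy() / bin_km).astype(int)
    counts = np.bincount(idx, minlength=len(edges) - 1)[:len(edges) - 1]
    sums = np.bincount(idx, weights=p["sit_fraction"].to_numpy(),
                       minlength=len(edges) - 1)[:len(edges) - 1]
    keep = counts >= eff_min
    if keep.sum() < 2:
        raise ProfileError(f"only {int(keep.sum())} bins with >= {eff_min} pairs")
    with np.errstate(invalid="ignore"):
        mean_pct = 100.0 * sums[keep] / counts[keep]
    return DistanceProfile(edges[:-1][keep], edges[1:][keep], mean_pct,
                           counts[keep], bin_km)


def _hinge_rss(x: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """RSS and coefficients of y = b0 + b1*x + b2*(x-psi)+ for each psi,
    batched over the candidate grid via 3x3 normal equations."""
    n = len(x)
    H = np.maximum(0.0, x[None, :] - grid[:, None])                  # (g, n)
    ones = np.broadcast_to(np.ones(n), H.shape)
    xx = np.broadcast_to(x, H.shape)
    X = np.stack([ones, xx, H], axis=2)                              # (g, n, 3)
    XtX = np.einsum("gni,gnj->gij", X, X)
    Xty = np.einsum("gni,n->gi", X, y)
    try:
        beta = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # rank-deficient candidates (possible in bootstrap resamples):
        # minimum-norm least squares still yields a valid RSS
        beta = np.einsum("gij,gj->gi", np.linalg.pinv(XtX), Xty)
    pred = np.einsum("gni,gi->gn", X, beta)
    rss = ((y[None, :] - pred) ** 2).sum(axis=1)
    return rss, beta


def _argmin_rss(rss: np.ndarray, rel_tol: float = 1e-8) -> int:
    """Index of the smallest candidate whose RSS ties the minimum to within
    numerical precision (ties broken towards the smaller breakpoint)."""
    lo = rss.min()
    return int(np.flatnonzero(rss <= lo + rel_tol * max(lo, 1.0))[0])


def _profile_grid(x: np.ndarray, bin_km: float, grid_step: float | None):
    step = bin_km / 10.0 if grid_step is None else grid_step
    lo, hi = x.min() + step, x.max() - step / 2
    grid = np.arange(lo, hi, step)
    return grid[(grid > x.min()) & (grid < x.max())]


def fit_breakpoint(profile: DistanceProfile, n_boot: int = 1000,
                   seed: int | None = None,
                   grid_step: float | None = None) -> BreakpointFit:
    """Continuous two-segment fit of the distance profile.

    The breakpoint is profiled over a fine grid (step = bin width / 10);
    at each candidate the remaining parameters are ordinary least squares,
    and the minimum-RSS candidate wins (ties -> smaller breakpoint).  The
    95% CI is a nonparametric percentile bootstrap over bins.
    """
    x = profile.centers_km.astype(float)
    y = profile.mean_sit_pct.astype(float)
    if len(x) < 4:
        raise ProfileError("need >= 4 bins to fit a breakpoint")
    grid = _profile_grid(x, profile.bin_km, grid_step)
    rss, beta = _hinge_rss(x, y, grid)
    if rss.max() - rss.min() < 1e-12:
        raise DegenerateFitError("RSS profile is flat across all candidates")
    k = _argmin_rss(rss)  # ties (to numerical precision) -> smaller breakpoint
    b0, b1, b2 = beta[k]
    psi = float(grid[k])
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        ii = rng.integers(0, len(x), len(x))
        xb, yb = x[ii], y[ii]
        if len(np.unique(xb)) < 4:
            continue
        gb = grid[(grid > xb.min()) & (grid < xb.max())]
        if len(gb) == 0:
            continue
        rb, _ = _hinge_rss(xb, yb, gb)
        boots.append(gb[_argmin_rss(rb)])
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo, hi = x.min(), x.max()
    ci = (float(min(lo, psi)), float(max(hi, psi)))
    return BreakpointFit(psi, ci, (float(b1), float(b1 + b2)), float(b0),
                         float(rss[k]), len(x))


def validate_interactions(approaches: list, fit: BreakpointFit,
                          require_fishing_min: bool = False) -> list:
    """Approach events reaching inside the interaction distance (closed
    boundary: min distance == breakpoint counts).

    With ``require_fishing_min=True`` the minimum-distance fix must be
    paired with a fishing-classified ping: interpolated steaming positions
    are too uncertain at the sub-interaction-distance scale to certify
    that a bird actually reached the vessel.
    """
    out = []
    for ev in approaches:
        if ev.min_distance_km > fit.breakpoint_km:
            continue
        if require_fishing_min and ev.activities is not None \
                and ev.activities[-1] != "fishing":
            continue
        out.append(ApproachEvent(ev.bird_id, ev.vessel_id, list(ev.fix_times),
                                 list(ev.distances_km), validated=True,
                                 activities=None if ev.activities is None
                                 else list(ev.activities)))
    return out


def diel_interaction_counts(events: list) -> pd.DataFrame:
    """Histogram of events over the 24 local (UTC+2) hours of day.

    The hour of an event is the local hour of its first fix; each hour
    carries a night flag from the solar calculator at the colony (computed
    per event date, an hour is night if any event in it was at night, and
    for empty hours from the median event date).
    """
    hours = np.arange(24)
    counts = np.zeros(24, dtype=int)
    night_votes = np.zeros(24, dtype=int)
    for ev in events:
        t_loc = to_local_time(pd.Timestamp(ev.fix_times[0]))
        counts[t_loc.hour] += 1
        if night_mask([t_loc])[0]:
            night_votes[t_loc.hour] += 1
    if events:
        ref_date = pd.Timestamp(
            sorted(pd.Timestamp(ev.fix_times[0]) for ev in events)
            [len(events) // 2]).normalize()
    else:
        ref_date = pd.Timestamp("2016-07-15")
    ref_night = night_mask(
        pd.DatetimeIndex([to_local_time(ref_date) + pd.Timedelta(hours=h, minutes=30)
                          for h in hours]))
    is_night = np.where(counts > 0, night_votes * 2 > counts, ref_night)
    return pd.DataFrame({"hour_local": hours, "n_events": counts,
                         "is_night": is_night})


def write_events(events: list, path) -> None:
    rows = [{
        "bird_id": ev.bird_id, "vessel_id": ev.vessel_id,
        "start": pd.Timestamp(ev.fix_times[0]).strftime("%Y-%m-%dT%H:%M:%S"),
        "end": pd.Timestamp(ev.fix_times[-1]).strftime("%Y-%m-%dT%H:%M:%S"),
        "start_distance_km": ev.start_distance_km,
        "min_distance_km": ev.min_distance_km,
        "validated": ev.validated,
    } for ev in events]
    pd.DataFrame(rows, columns=["bird_id", "vessel_id", "start", "end",
                                "start_distance_km", "min_distance_km",
                                "validated"]).to_csv(path, index=False)
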