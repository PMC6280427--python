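import numpy as np
import pandas as pd
import pytest

from vesselbird import interaction as ia
from vesselbird.geo import DomainError
from vesselbird.simulate import simulate_profile_pairs, sit_probability


def _pairs_from_series(dists, bird="b1", vessel="v1",
                       t0="2016-07-01 10:00", step_min=5):
    t0 = pd.Timestamp(t0)
    return pd.DataFrame({
        "bird_id": bird, "vessel_id": vessel,
        "t": [t0 + pd.Timedelta(minutes=step_min * i)
              for i in range(len(dists))],
        "distance_km": dists})


class TestMatchPairs:
    def _fixes(self, times):
        return pd.DataFrame({"bird_id": "b1", "t": pd.to_datetime(times),
                             "lat": 35.0, "lon": 12.0})

    def _grid(self, times, lat=35.0, lon=12.05):
        return pd.DataFrame({"vessel_id": "v1", "t": pd.to_datetime(times),
                             "lat": lat, "lon": lon,
                             "speed_kn": 3.0, "heading_deg": 0.0,
                             "gear": "trawl", "activity": "fishing"})

    def test_half_open_window_selects_single_ping(self):
        fixes = self._fixes(["2016-07-01 10:02"])
        grid = self._grid(["2016-07-01 10:00", "2016-07-01 10:10"])
        out = ia.match_pairs(fixes, grid)
        assert len(out) == 1
        assert out["grid_t"].iloc[0] == pd.Timestamp("2016-07-01 10:00")

    def test_simultaneous_fix_matches_its_own_instant(self):
        fixes = self._fixes(["2016-07-01 10:00"])
        grid = self._grid(["2016-07-01 10:00", "2016-07-01 10:10"])
        out = ia.match_pairs(fixes, grid)
        assert out["grid_t"].iloc[0] == pd.Timestamp("2016-07-01 10:00")

    def test_vessel_beyond_radius_dropped(self):
        fixes = self._fixes(["2016-07-01 10:02"])
        grid = self._grid(["2016-07-01 10:00"], lat=35.0, lon=13.0)  # ~90 km
        assert len(ia.match_pairs(fixes, grid, radius_km=50)) == 0

    def test_no_vessels_in_range_gives_empty(self):
        fixes = self._fixes(["2016-07-01 10:02"])
        out = ia.match_pairs(fixes, self._grid([]))
        assert len(out) == 0

    def test_fishing_only_switch(self):
        fixes = self._fixes(["2016-07-01 10:02"])
        grid = self._grid(["2016-07-01 10:00"])
        grid["activity"] = "steaming"
        assert len(ia.match_pairs(fixes, grid, fishing_only=True)) == 0
        assert len(ia.match_pairs(fixes, grid, fishing_only=False)) == 1


class TestApproaches:
    def test_hand_traced_run(self):
        pairs = _pairs_from_series([20.0, 15.0, 10.0, 12.0])
        events = ia.detect_approaches(pairs)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_distance_km == 20.0
        assert ev.min_distance_km == 10.0
        assert len(ev.fix_times) == 3

    def test_small_total_drop_rejected(self):
        pairs = _pairs_from_series([10.0, 9.8, 9.7])
        assert ia.detect_approaches(pairs) == []

    def test_run_trimmed_to_attraction_distance(self):
        pairs = _pairs_from_series([35.0, 28.0, 20.0])
        events = ia.detect_approaches(pairs)
        assert len(events) == 1
        assert events[0].start_distance_km == 28.0

    def test_per_step_reading_of_the_drop_rule(self):
        pairs = _pairs_from_series([10.0, 9.3, 8.9])  # steps 0.7, 0.4
        assert len(ia.detect_approaches(pairs)) == 1
        assert ia.detect_approaches(pairs, per_step_drop=True) == []

    def test_temporal_gap_breaks_a_run(self):
        pairs = _pairs_from_series([20.0, 15.0])
        late = _pairs_from_series([10.0, 5.0], t0="2016-07-01 12:00")
        both = pd.concat([pairs, late], ignore_index=True)
        events = ia.detect_approaches(both)
        assert len(events) == 2

    def test_invariant_to_interleaved_unrelated_vessels(self):
        pairs = _pairs_from_series([20.0, 15.0, 10.0, 12.0])
        other = _pairs_from_series([40.0, 41.0, 39.0, 42.0], vessel="v2")
        mixed = (pd.concat([other, pairs], ignore_index=True)
                 .sample(frac=1, random_state=0))
        ev1 = ia.detect_approaches(pairs)
        ev2 = [e for e in ia.detect_approaches(mixed) if e.vessel_id == "v1"]
        assert len(ev1) == len(ev2) == 1
        assert ev1[0].distances_km == ev2[0].distances_km

    def test_event_invariants_enforced(self):
        with pytest.raises(DomainError):
            ia.ApproachEvent("b", "v", [pd.Timestamp("2016-07-01")], [5.0])
        with pytest.raises(DomainError):
            ia.ApproachEvent("b", "v",
                             list(pd.date_range("2016-07-01", periods=2,
                                                freq="5min")),
                             [5.0, 6.0])


class TestDistanceProfile:
    def test_zero_sitting_gives_zero_means(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame({"bird_id": "b", "vessel_id": "v",
                              "t": pd.Timestamp("2016-07-01"),
                              "distance_km": rng.uniform(0, 3, 2000),
                              "sit_fraction": 0.0})
        prof = ia.build_distance_profile(pairs, max_km=5)
        assert (prof.mean_sit_pct == 0.0).all()

    def test_half_open_bin_boundary(self):
        pairs = pd.DataFrame({"bird_id": "b", "vessel_id": "v",
                              "t": pd.Timestamp("2016-07-01"),
                              "distance_km": [0.25] * 10 + [0.1] * 10,
                              "sit_fraction": [1.0] * 10 + [0.0] * 10})
        prof = ia.build_distance_profile(pairs, min_count=5)
        # 0.25 km falls in the second bin [0.25, 0.50)
        second = prof.mean_sit_pct[prof.bin_lo_km == 0.25]
        first = prof.mean_sit_pct[prof.bin_lo_km == 0.0]
        assert second[0] == 100.0 and first[0] == 0.0

    def test_bin_means_track_planted_ramp_within_3se(self):
        d_star, p_in, p_out = 1.28, 0.8, 0.2
        pairs = simulate_profile_pairs(20000, d_star, p_in, p_out, seed=4)
        prof = ia.build_distance_profile(pairs, max_km=5)
        centers = prof.centers_km
        expect = 100 * sit_probability(centers, d_star, p_in, p_out)
        se = 100 * np.sqrt(expect / 100 * (1 - expect / 100) / prof.counts)
        assert (np.abs(prof.mean_sit_pct - expect) <= 3 * se + 1e-9).all()

    def test_too_few_bins_raise(self):
        pairs = pd.DataFrame({"bird_id": "b", "vessel_id": "v",
                              "t": pd.Timestamp("2016-07-01"),
                              "distance_km": [0.1] * 50,
                              "sit_fraction": 0.5})
        with pytest.raises(ia.ProfileError):
            ia.build_distance_profile(pairs)


def brute_force_breakpoint(x, y, grid, rel_tol=1e-8):
    """Independent exhaustive search: fit y ~ 1 + x + max(0, x-psi) by
    lstsq at every candidate; the smallest psi whose RSS ties the global
    minimum to numerical precision wins."""
    rss = []
    for psi in grid:
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss.append(float(((y - X @ beta) ** 2).sum()))
    rss = np.asarray(rss)
    lo = rss.min()
    return grid[np.flatnonzero(rss <= lo + rel_tol * max(lo, 1.0))[0]]


class TestBreakpoint:
    def _profile(self, x, y, bin_km=0.25):
        return ia.DistanceProfile(x - bin_km / 2, x + bin_km / 2, y,
                                  np.full(len(x), 200), bin_km)

    def test_noiseless_knee_recovered_to_grid_resolution(self):
        x = np.arange(0.125, 5.0, 0.25)
        y = 100 * sit_probability(x, 1.28, 0.8, 0.2)
        fit = ia.fit_breakpoint(self._profile(x, y), n_boot=50, seed=0)
        assert abs(fit.breakpoint_km - 1.28) <= 0.0125 + 1e-9
        assert fit.slopes[0] < -1 and abs(fit.slopes[1]) < 1

    def test_straight_line_is_degenerate(self):
        x = np.arange(0.125, 5.0, 0.25)
        y = 30.0 - 2.0 * x
        with pytest.raises(ia.DegenerateFitError):
            ia.fit_breakpoint(self._profile(x, y), n_boot=10, seed=0)

    def test_straight_line_with_noise_flagged_by_wide_ci(self):
        rng = np.random.default_rng(5)
        x = np.arange(0.125, 5.0, 0.25)
        y = 30.0 - 2.0 * x + rng.normal(0, 0.5, len(x))
        fit = ia.fit_breakpoint(self._profile(x, y), n_boot=300, seed=5)
        assert fit.ci95[1] - fit.ci95[0] > 0.5 * (x.max() - x.min())

    def test_grid_minimiser_equals_brute_force_on_random_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = np.arange(0.125, 0.125 + 12 * 0.25, 0.25)
            y = rng.uniform(0, 100, 12)
            prof = self._profile(x, y)
            fit = ia.fit_breakpoint(prof, n_boot=0, seed=0)
            grid = ia._profile_grid(x, 0.25, None)
            assert fit.breakpoint_km == pytest.approx(
                brute_force_breakpoint(x, y, grid), abs=1e-12)

    def test_breakpoint_inside_ci(self):
        pairs = simulate_profile_pairs(6000, 1.28, seed=9)
        prof = ia.build_distance_profile(pairs, max_km=5)
        fit = ia.fit_breakpoint(prof, n_boot=200, seed=9)
        assert fit.ci95[0] <= fit.breakpoint_km <= fit.ci95[1]


class TestValidation:
    def _ev(self, dists, activities=None):
        t = list(pd.date_range("2016-07-01", periods=len(dists), freq="5min"))
        return ia.ApproachEvent("b", "v", t, dists, activities=activities)

    def _fit(self, bp=1.28):
        return ia.BreakpointFit(bp, (bp - 0.1, bp + 0.1), (-50.0, 0.0),
                                80.0, 1.0, 10)

    def test_reaching_inside_is_interaction(self):
        out = ia.validate_interactions([self._ev([5.0, 1.0])], self._fit())
        assert len(out) == 1 and out[0].validated

    def test_stopping_outside_is_not(self):
        assert ia.validate_interactions([self._ev([5.0, 2.0])],
                                        self._fit()) == []

    def test_closed_boundary(self):
        out = ia.validate_interactions([self._ev([5.0, 1.28])], self._fit())
        assert len(out) == 1

    def test_fishing_requirement_at_minimum(self):
        ev = self._ev([5.0, 1.0], activities=["fishing", "steaming"])
        assert ia.validate_interactions([ev], self._fit(),
                                        require_fishing_min=True) == []
        ev2 = self._ev([5.0, 1.0], activities=["steaming", "fishing"])
        assert len(ia.validate_interactions([ev2], self._fit(),
                                            require_fishing_min=True)) == 1

    def test_validation_only_filters(self):
        events = [self._ev([5.0, d]) for d in (0.5, 1.0, 2.0, 3.0)]
        out = ia.validate_interactions(events, self._fit())
        kept = {e.min_distance_km for e in out}
        assert kept <= {e.min_distance_km for e in events}
        assert all(e.min_distance_km <= 1.28 for e in out)


class TestDiel:
    def _ev_at(self, local_hhmm):
        # events are stored in UTC; build from a local (UTC+2) clock time
        t_utc = (pd.Timestamp(f"2016-07-10 {local_hhmm}")
                 - pd.Timedelta(hours=2))
        t = [t_utc, t_utc + pd.Timedelta(minutes=5)]
        return ia.ApproachEvent("b", "v", t, [5.0, 1.0], validated=True)

    def test_hourly_histogram(self):
        events = [self._ev_at("06:10"), self._ev_at("06:40"),
                  self._ev_at("19:05")]
        out = ia.diel_interaction_counts(events)
        assert out.loc[out["hour_local"] == 6, "n_events"].iloc[0] == 2
        assert out.loc[out["hour_local"] == 19, "n_events"].iloc[0] == 1
        assert out["n_events"].sum() == 3

    def test_empty_input_gives_zero_histogram(self):
        out = ia.diel_interaction_counts([])
        assert (out["n_events"] == 0).all() and len(out) == 24

    def test_night_flag_midday_vs_midnight(self):
        out = ia.diel_interaction_counts([self._ev_at("13:30"),
                                          self._ev_at("01:30")])
        assert not out.loc[out["hour_local"] == 13, "is_night"].iloc[0]
        assert out.loc[out["hour_local"] == 1, "is_night"].iloc[0]
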