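import json
import time

import numpy as np
import pandas as pd
import pytest

from vesselbird import behaviour as bh
from vesselbird.simulate import (SimConfig, SimDataset,
                                 behaviour_labels_from_states,
                                 simulate_vessel_tracks, synthesize_accel)


class TestReproducibility:
    def test_fixed_seed_reproduces_streams(self):
        cfg = SimConfig(n_birds=2, n_vessels=3, days=0.5, seed=21)
        a, b = SimDataset(cfg), SimDataset(cfg)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(a.native_pings, b.native_pings)
        for bid in a.truth.labels_by_bird:
            np.testing.assert_array_equal(a.truth.labels_by_bird[bid][1],
                                          b.truth.labels_by_bird[bid][1])

    def test_emit_is_byte_identical(self, tmp_path):
        cfg = SimConfig(n_birds=1, n_vessels=2, days=0.25, seed=8)
        m1 = SimDataset(cfg).emit(tmp_path / "a")
        m2 = SimDataset(cfg).emit(tmp_path / "b")
        assert m1 == m2
        for name in ("bird_gps.csv", "vms_native.csv", "ground_truth.json",
                     "manifest.json", "behaviour_truth.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())


class TestPlantedStructure:
    def test_no_scavengers_means_no_interactions(self):
        sim = SimDataset(SimConfig(n_birds=4, n_vessels=5, days=1.5,
                                   frac_scavengers=0.0, seed=5))
        assert sim.truth.interactions == []
        assert sim.truth.diversions == []

    def test_planted_interactions_reach_inside_d_star(self, small_sim):
        d_star = small_sim.cfg.true_interaction_km
        assert len(small_sim.truth.interactions) > 0
        for ev in small_sim.truth.interactions:
            assert ev.min_distance_km <= d_star

    def test_ground_truth_labels_cover_every_second(self, small_sim):
        n_sec = int(small_sim.cfg.days * 86400)
        for bid, (t0, codes) in small_sim.truth.labels_by_bird.items():
            assert len(codes) == n_sec

    def test_trip_records_self_consistent(self, small_sim):
        """Planted trip max distance matches the per-minute truth within
        one fix step."""
        step_km = (small_sim.cfg.bird_flight_speed_ms * 60
                   * small_sim.cfg.gps_step_min / 1000)
        from vesselbird.simulate import KM_PER_DEG_LAT
        for _, trip in small_sim.truth.trips.iterrows():
            bt = small_sim.bird_truth[trip["bird_id"]]
            m0 = int((trip["start"] - small_sim.t0).total_seconds() / 60)
            m1 = int((trip["end"] - small_sim.t0).total_seconds() / 60)
            max_min = np.hypot(bt["x"][m0:m1 + 1], bt["y"][m0:m1 + 1]).max()
            assert abs(max_min - trip["max_colony_distance_km"]) <= step_km

    def test_zero_duration_simulation_is_empty(self):
        sim = SimDataset(SimConfig(n_birds=2, n_vessels=2, days=0, seed=3))
        assert len(sim.fixes) == 0 and len(sim.native_pings) == 0


class TestVessels:
    def test_gear_mix_matches_fleet_proportions(self):
        cfg = SimConfig(n_vessels=150, days=0.25, seed=13)
        _, truth = simulate_vessel_tracks(cfg, np.random.default_rng(13))
        gears = [v["gear"] for v in truth.values()]
        frac = np.mean([g == "trawl" for g in gears])
        p = 0.76
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 150)

    def test_fishing_ping_speeds_inside_configured_band(self, small_sim):
        ok = total = 0
        t0 = small_sim.t0
        for _, ping in small_sim.native_pings.iterrows():
            m = int((ping["t"] - t0).total_seconds() / 60)
            vt = small_sim.vessel_truth[ping["vessel_id"]]
            if not vt["fishing"][m]:
                continue
            lo, hi = small_sim.cfg.fishing_speed_kn[ping["gear"]]
            total += 1
            ok += lo <= ping["speed_kn"] <= hi
        assert total > 0 and ok / total >= 0.95

    def test_native_ping_intervals_in_configured_range(self, small_sim):
        for _, g in small_sim.native_pings.groupby("vessel_id"):
            dt = g["t"].diff().dropna().dt.total_seconds() / 60
            assert (dt >= small_sim.cfg.vms_native_step_min[0] - 1).all()
            assert (dt <= small_sim.cfg.vms_native_step_min[1] + 1).all()


class TestAccelArchetypes:
    def _labels(self, code, seconds):
        return np.full(seconds, bh.LABEL_CODES[code], dtype=np.uint8)

    def test_pure_sit_hour_classified_sitting(self):
        cfg = SimConfig()
        acc = synthesize_accel(self._labels("SIT", 3600), cfg,
                               np.random.default_rng(0), "b", "2016-07-01")
        v = bh.compute_vedba(acc)
        flags = bh.classify_sitting(v.per_second, np.zeros(3600))
        assert flags.mean() >= 0.95

    def test_pure_glide_hour_not_sitting(self):
        cfg = SimConfig()
        acc = synthesize_accel(self._labels("GLIDE", 3600), cfg,
                               np.random.default_rng(1), "b", "2016-07-01")
        v = bh.compute_vedba(acc)
        flags = bh.classify_sitting(v.per_second, np.zeros(3600))
        assert flags.mean() < 0.05

    def test_flapping_spectral_peak_at_wingbeat(self):
        cfg = SimConfig()
        acc = synthesize_accel(self._labels("FLAP", 120), cfg,
                               np.random.default_rng(2), "b", "2016-07-01")
        amp = np.abs(np.fft.rfft(np.abs(acc.az)))
        freqs = np.fft.rfftfreq(len(acc.az), d=1.0 / cfg.accel_rate_hz)
        peak = freqs[1:][np.argmax(amp[1:])]
        assert abs(peak - cfg.wingbeat_hz) <= 0.5

    def test_glide_bouts_bounded_by_flaps(self):
        states = np.array([1] * 120, dtype=np.uint8)  # 2 h commute
        codes = behaviour_labels_from_states(states, np.random.default_rng(4))
        glide = codes == bh.LABEL_CODES["GLIDE"]
        flap = codes == bh.LABEL_CODES["FLAP"]
        idx = np.flatnonzero(glide)
        assert len(idx) > 0
        for i in idx:
            assert flap[:i].any() and flap[i:].any()


class TestEmit:
    def test_emitted_files_parse_back(self, tmp_path):
        cfg = SimConfig(n_birds=1, n_vessels=2, days=0.25, seed=8)
        sim = SimDataset(cfg)
        sim.emit(tmp_path)
        from vesselbird.geo import read_bird_gps, read_vessel_pings
        gps = read_bird_gps(tmp_path / "bird_gps.csv")
        assert len(gps) == len(sim.fixes)
        pings = read_vessel_pings(tmp_path / "vms_native.csv")
        assert len(pings) == len(sim.native_pings)
        acc = bh.read_accel_csv(tmp_path / "accel_B000.csv", bird_id="B000")
        assert acc.rate_hz == pytest.approx(cfg.accel_rate_hz)
        assert len(acc) == int(cfg.days * 86400) * cfg.accel_rate_hz
        gt = json.loads((tmp_path / "ground_truth.json").read_text())
        assert gt["true_interaction_km"] == cfg.true_interaction_km

    def test_reference_dataset_emits_within_budget(self, tmp_path):
        t0 = time.time()
        SimDataset(SimConfig(n_birds=5, n_vessels=10, days=3, seed=2)).emit(
            tmp_path / "ref")
        assert time.time() - t0 < 120.0
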