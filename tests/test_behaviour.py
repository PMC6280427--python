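import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from vesselbird import behaviour as bh
from vesselbird.geo import DomainError
from vesselbird.simulate import (SimConfig, behaviour_labels_from_states,
                                 synthesize_accel)

RATE = 25


def _acc(ax, ay, az, t0="2016-07-01", bird="b"):
    return bh.AccelSeries(bird, pd.Timestamp(t0), RATE, ax, ay, az)


class TestVedba:
    def test_static_stream_has_zero_vedba(self):
        n = 120 * RATE
        acc = _acc(np.zeros(n), np.zeros(n), np.ones(n))
        v = bh.compute_vedba(acc)
        assert v.vedba.max() < 1e-9

    def test_unit_dynamic_components_give_sqrt3_exactly(self):
        assert bh.vedba_norm(1.0, 1.0, 1.0) == np.sqrt(3.0)

    def test_sinusoid_mean_matches_quadrature_oracle(self):
        # mean of |A sin(2 pi f t)| over one second, computed numerically
        A, f = 0.5, 4.0
        expected, _ = quad(lambda t: abs(A * np.sin(2 * np.pi * f * t)), 0, 1)
        n = 60 * RATE
        t = np.arange(n) / RATE
        acc = _acc(np.zeros(n), np.zeros(n), 1.0 + A * np.sin(2 * np.pi * f * t))
        v = bh.compute_vedba(acc)
        mid = v.per_second[5:55].mean()
        assert mid == pytest.approx(expected, rel=0.05)

    def test_axis_permutation_and_sign_invariance(self):
        rng = np.random.default_rng(3)
        n = 30 * RATE
        a = rng.normal(0, 0.2, (3, n)) + np.array([[0.0], [0.0], [1.0]])
        base = bh.compute_vedba(_acc(*a)).vedba
        for perm in [(1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            v = bh.compute_vedba(_acc(*a[list(perm)])).vedba
            np.testing.assert_allclose(v, base, atol=1e-12)
        flipped = bh.compute_vedba(_acc(a[0], -a[1], a[2])).vedba
        np.testing.assert_allclose(flipped, base, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            bh.compute_vedba(_acc(np.zeros(5), np.zeros(5), np.ones(5)))


class TestSitting:
    @pytest.mark.parametrize("vedba,speed,expected", [
        (0.5, 0.5, True),    # inside the 0.1-1 g band, slow
        (1.5, 0.5, False),   # above the band
        (0.05, 0.0, False),  # below the band
        (0.5, 5.0, False),   # in band but moving fast
    ])
    def test_band_and_speed_rules(self, vedba, speed, expected):
        out = bh.classify_sitting(np.array([vedba]), np.array([speed]))
        assert bool(out[0]) is expected

    def test_misaligned_series_rejected(self):
        with pytest.raises(DomainError):
            bh.classify_sitting(np.zeros(10), np.zeros(9))


class TestFlapping:
    def _alternating_stream(self, seed=0, blocks=10, block_s=30):
        rng = np.random.default_rng(seed)
        z, truth = [], []
        for k in range(blocks):
            n = block_s * RATE
            t = np.arange(n) / RATE
            if k % 2 == 0:
                z.append(1 + 1.0 * np.sin(2 * np.pi * 4 * t)
                         + rng.normal(0, 0.03, n))
                truth += [True] * block_s
            else:
                z.append(1 + rng.normal(0, 0.03, n))
                truth += [False] * block_s
        n_tot = blocks * block_s * RATE
        acc = _acc(rng.normal(0, 0.03, n_tot), rng.normal(0, 0.03, n_tot),
                   np.concatenate(z))
        return acc, np.array(truth)

    def test_alternating_sinusoid_recovered(self):
        acc, truth = self._alternating_stream()
        flap = bh.detect_flapping(acc)
        assert (flap == truth).mean() >= 0.95

    def test_pure_noise_yields_no_flapping(self):
        rng = np.random.default_rng(1)
        n = 300 * RATE
        acc = _acc(rng.normal(0, 0.03, n), rng.normal(0, 0.03, n),
                   1 + rng.normal(0, 0.03, n))
        assert bh.detect_flapping(acc).sum() == 0

    def test_constant_signal_yields_no_flapping(self):
        n = 60 * RATE
        acc = _acc(np.zeros(n), np.zeros(n), np.ones(n))
        assert bh.detect_flapping(acc).sum() == 0

    def test_amplitude_scaling_leaves_labels_unchanged(self):
        acc, _ = self._alternating_stream()
        doubled = _acc(acc.ax, acc.ay, 1 + 2 * (acc.az - 1))
        np.testing.assert_array_equal(bh.detect_flapping(acc),
                                      bh.detect_flapping(doubled))

    def test_too_short_stream_rejected(self):
        with pytest.raises(DomainError):
            bh.detect_flapping(_acc(np.zeros(50), np.zeros(50), np.ones(50)))


class TestGliding:
    def test_short_gap_between_flaps_is_glide(self):
        flags = np.array([True] * 5 + [False] * 10 + [True] * 5)
        glide = bh.infer_gliding(flags)
        assert glide[5:15].all() and not glide[:5].any() and not glide[15:].any()

    def test_long_gap_is_not_glide(self):
        flags = np.array([True] * 5 + [False] * 300 + [True] * 5)
        assert not bh.infer_gliding(flags).any()

    def test_leading_and_trailing_gaps_never_glide(self):
        flags = np.array([False] * 8 + [True] * 5 + [False] * 8)
        assert not bh.infer_gliding(flags).any()


class TestEthogram:
    def test_labels_partition_recorded_time(self):
        cfg = SimConfig()
        states = np.array([0] * 20 + [1] * 40 + [3] * 40 + [2] * 20,
                          dtype=np.uint8)
        codes = behaviour_labels_from_states(states, np.random.default_rng(5))
        acc = synthesize_accel(codes, cfg, np.random.default_rng(6), "b",
                               "2016-07-01")
        speed = np.where(np.isin(np.repeat(states, 60), (1, 2)), 10.0, 0.2)
        labels, _ = bh.build_ethogram(acc, speed)
        assert len(labels) == len(codes)
        assert set(np.unique(labels)) <= set(bh.LABELS)
        segs = bh.segments_from_labels(labels, acc.t0, "b")
        # contiguous, non-overlapping, exhaustive
        assert (segs["start"].iloc[1:].to_numpy()
                == segs["end"].iloc[:-1].to_numpy()).all()
        total = (segs["end"] - segs["start"]).sum()
        assert total == pd.Timedelta(seconds=len(labels))

    def test_ethogram_round_trip_io(self, tmp_path):
        labels = np.array(["SIT"] * 10 + ["FLAP"] * 5 + ["OTHER"] * 5,
                          dtype=object)
        segs = bh.segments_from_labels(labels, "2016-07-01", "b")
        p = tmp_path / "eth.csv"
        bh.write_ethogram(segs, p)
        back = bh.read_ethogram(p)
        assert list(back["label"]) == ["SIT", "FLAP", "OTHER"]


class TestDailySummaries:
    def test_six_hour_flight_day(self):
        # one 6-h flapping block starting at local midnight
        t0 = pd.Timestamp("2016-06-30 22:00")  # == 2016-07-01 00:00 local
        n_sec = 24 * 3600
        labels = np.array(["FLAP"] * (6 * 3600) + ["OTHER"] * (18 * 3600),
                          dtype=object)
        v = bh.VedbaSeries("b", t0, RATE, np.zeros(10), np.full(n_sec, 0.2))
        out = bh.daily_summaries(labels, v)
        assert len(out) == 1
        assert out["daily_flight_time_h"].iloc[0] == pytest.approx(6.0)

    def test_constant_vedba_sums_per_interval(self):
        # constant per-second VeDBA c over k complete 5-min intervals
        t0 = pd.Timestamp("2016-06-30 22:00")
        k, c = 288, 0.25
        n_sec = k * 300
        labels = np.array(["SIT"] * n_sec, dtype=object)
        v = bh.VedbaSeries("b", t0, RATE, np.zeros(10), np.full(n_sec, c))
        out = bh.daily_summaries(labels, v)
        assert out["daily_vedba_sum"].iloc[0] == pytest.approx(k * c)

    def test_planted_flight_hours_recovered_from_accel(self):
        # a synthetic local day carrying 6.22 h of flight
        cfg = SimConfig()
        flight_min = int(round(6.22 * 60))
        states = np.array([1] * flight_min + [3] * (1440 - flight_min),
                          dtype=np.uint8)
        rng = np.random.default_rng(7)
        codes = behaviour_labels_from_states(states, rng)
        t0 = pd.Timestamp("2016-06-30 22:00")
        acc = synthesize_accel(codes, cfg, rng, "b", t0)
        speed = np.where(np.repeat(states, 60) == 1, 10.0, 0.2)
        labels, v = bh.build_ethogram(acc, speed)
        out = bh.daily_summaries(labels, v)
        assert out["daily_flight_time_h"].iloc[0] == pytest.approx(6.22, abs=0.1)


class TestGroundSpeed:
    def test_segment_speed_is_constant_within_segment(self):
        from tests.conftest import toy_fixes
        # two 5-min segments: ~666 m then 0 m along a meridian
        lat0 = 35.0
        dlat = 2.0 / 3.0 / 111.19492664455873  # 666.67 m
        gps = toy_fixes("b", "2016-07-01", [lat0, lat0 + dlat, lat0 + dlat],
                        [12.0, 12.0, 12.0])
        speed = bh.ground_speed_per_second(gps, "2016-07-01", 600)
        assert speed[10] == pytest.approx(666.67 / 300, rel=1e-3)
        assert speed[400] == pytest.approx(0.0, abs=1e-9)
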