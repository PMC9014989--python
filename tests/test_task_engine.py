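"""Unit and property tests for the multitasking simulator and its scoring."""

import dataclasses

import numpy as np
import pytest

from flightload.errors import ConfigurationError, MetricError
from flightload.task_engine import (BehaviorLog, MeterEvent, OperatorProfile,
                                    TaskConfig, allocate_resources,
                                    read_behavior_log, score_performance,
                                    simulate_session, write_behavior_log)


class TestAllocateResources:
    def test_single_consumer_takes_all(self, default_profile):
        shares = allocate_resources(default_profile, {"tracking"}, {"tracking": 1.0})
        assert shares == {"tracking": 1.0}

    def test_greedy_fill_by_priority(self):
        profile = OperatorProfile(priority_order=("tracking", "meter", "residual"),
                                  demands={"tracking": 0.6, "meter": 0.6, "residual": 0.3})
        shares = allocate_resources(profile, {"tracking", "meter", "residual"},
                                    {"tracking": 0.6, "meter": 0.6, "residual": 0.3})
        assert shares == {"tracking": 0.6, "meter": pytest.approx(0.4), "residual": 0.0}

    def test_empty_pool_gives_zero_shares(self, default_profile):
        profile = dataclasses.replace(default_profile, capacity=0.0)
        shares = allocate_resources(profile, {"tracking", "residual"},
                                    {"tracking": 0.5, "residual": 0.5})
        assert all(v == 0.0 for v in shares.values())

    def test_primaries_served_before_residual(self, default_profile):
        shares = allocate_resources(
            default_profile, {"tracking", "meter", "residual"},
            {"tracking": 0.85, "meter": 0.3, "residual": 0.6})
        assert shares["meter"] == pytest.approx(0.3)
        assert shares["residual"] <= shares["tracking"]
        assert sum(shares.values()) <= default_profile.capacity + 1e-12

    def test_unknown_task_rejected(self, default_profile):
        with pytest.raises(ConfigurationError):
            allocate_resources(default_profile, {"warp_drive"}, {"warp_drive": 1.0})


class TestSimulateSession:
    def test_low_condition_has_no_meter_or_emergency_events(self, default_profile):
        log = simulate_session(TaskConfig(condition="low", rng_seed=3), default_profile)
        assert log.meter_events == ()
        assert log.emergency_events == ()
        assert len(log.numeral_events) > 0

    def test_noiseless_operator_never_drifts(self, default_profile):
        profile = dataclasses.replace(default_profile, tracking_noise_sd=0.0)
        cfg = TaskConfig(condition="low", rng_seed=1)
        log = simulate_session(cfg, profile)
        assert np.all(log.tracking_distance_mm == 0.0)
        assert score_performance(log, cfg).n_alarms == 0

    def test_same_seed_reproduces_identical_logs(self, tmp_path, default_profile):
        cfg = TaskConfig(condition="high", rng_seed=11)
        a = simulate_session(cfg, default_profile)
        b = simulate_session(cfg, default_profile)
        for i, log in enumerate((a, b)):
            write_behavior_log(log, tmp_path / f"{i}.jsonl", tmp_path / f"{i}.csv")
        assert (tmp_path / "0.jsonl").read_bytes() == (tmp_path / "1.jsonl").read_bytes()
        assert (tmp_path / "0.csv").read_bytes() == (tmp_path / "1.csv").read_bytes()

    def test_emergency_lifetimes_and_gaps(self, default_profile):
        cfg = TaskConfig(condition="high", rng_seed=5)
        log = simulate_session(cfg, default_profile)
        onsets = [ev.onset_s for ev in log.emergency_events]
        assert len(onsets) >= 2
        for ev in log.emergency_events:
            if ev.response_s is not None:
                assert 0 <= ev.response_s - ev.onset_s <= cfg.emergency_window_s
            assert 10 <= ev.dot_count <= 20
        gaps = np.diff(onsets)
        assert np.all(gaps >= cfg.emergency_gap_s - 1e-9)

    def test_event_times_within_run(self, default_profile):
        cfg = TaskConfig(condition="high", rng_seed=2)
        log = simulate_session(cfg, default_profile)
        for ev in log.meter_events + log.emergency_events:
            assert 0 <= ev.onset_s <= cfg.duration_s
            if ev.response_s is not None:
                assert ev.onset_s <= ev.response_s <= cfg.duration_s
        for ev in log.numeral_events:
            assert 0 <= ev.shown_s <= ev.response_s <= cfg.duration_s

    def test_nonpositive_tick_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            TaskConfig(condition="low", tick_hz=0.0)


class TestScorePerformance:
    @staticmethod
    def _log_with_distance(t, d, condition="low", **kw):
        return BehaviorLog(condition=condition, tracking_t_s=t, tracking_distance_mm=d,
                           alarm_events=(), meter_events=kw.get("meter_events", ()),
                           emergency_events=(), numeral_events=kw.get("numeral_events", ()),
                           seed=0, duration_s=180.0)

    def test_constant_distance_below_threshold(self):
        cfg = TaskConfig(condition="low")
        t = np.arange(0, 180, 0.05)
        log = self._log_with_distance(t, np.full(t.size, 10.0))
        perf = score_performance(log, cfg)
        assert perf.avg_distance_mm == pytest.approx(10.0)
        assert perf.n_alarms == 0

    def test_single_excursion_counts_one_alarm_onset(self):
        cfg = TaskConfig(condition="low")
        t = np.arange(0, 180, 0.05)
        d = np.full(t.size, 10.0)
        d[(t >= 50.0) & (t < 55.0)] = 35.0  # one contiguous 5-s excursion
        perf = score_performance(self._log_with_distance(t, d), cfg)
        assert perf.n_alarms == 1

    def test_per_check_mode_counts_every_check(self):
        cfg = TaskConfig(condition="low", alarm_mode="per_check")
        t = np.arange(0, 180, 0.05)
        d = np.full(t.size, 10.0)
        d[(t >= 50.0) & (t < 55.0)] = 35.0
        perf = score_performance(self._log_with_distance(t, d), cfg)
        assert perf.n_alarms == 5

    def test_meter_rt_and_accuracy_hand_example(self):
        cfg = TaskConfig(condition="medium")
        events = (MeterEvent(10.0, 12.0, True), MeterEvent(40.0, 43.0, True),
                  MeterEvent(70.0, 74.0, True), MeterEvent(100.0, None, False))
        t = np.arange(0, 180, 0.05)
        log = self._log_with_distance(t, np.full(t.size, 5.0), condition="medium",
                                      meter_events=events)
        perf = score_performance(log, cfg)
        assert perf.meter_rt_s == pytest.approx(3.0)
        assert perf.meter_accuracy_pct == pytest.approx(75.0)

    def test_none_pattern_matches_condition(self, default_profile):
        for condition in ("low", "medium", "high"):
            cfg = TaskConfig(condition=condition, rng_seed=4)
            perf = score_performance(simulate_session(cfg, default_profile), cfg)
            assert (perf.meter_rt_s is None) == (condition == "low")
            assert (perf.emergency_rt_s is None) == (condition != "high")

    def test_empty_tracking_is_an_error(self):
        cfg = TaskConfig(condition="low")
        log = self._log_with_distance(np.array([]), np.array([]))
        with pytest.raises(MetricError):
            score_performance(log, cfg)


class TestLoadOrdering:
    """Monte-Carlo checks of the qualitative load-performance pattern."""

    N_SEEDS = 150

    @pytest.fixture(scope="class")
    @classmethod
    def condition_means(cls):
        profile = OperatorProfile()
        out = {}
        for condition in ("low", "medium", "high"):
            d, a, n = [], [], []
            for seed in range(cls.N_SEEDS):
                cfg = TaskConfig(condition=condition, rng_seed=seed)
                perf = score_performance(simulate_session(cfg, profile), cfg)
                d.append(perf.avg_distance_mm)
                a.append(perf.n_alarms)
                n.append(perf.n_numeral_responses)
            out[condition] = (np.mean(d), np.mean(a), np.mean(n))
        return out

    def test_distance_and_alarms_increase_with_load(self, condition_means):
        d = [condition_means[c][0] for c in ("low", "medium", "high")]
        a = [condition_means[c][1] for c in ("low", "medium", "high")]
        assert d[0] <= d[1] <= d[2]
        assert a[0] <= a[1] <= a[2]

    def test_numeral_responses_decrease_with_load(self, condition_means):
        n = [condition_means[c][2] for c in ("low", "medium", "high")]
        assert n[0] >= n[1] >= n[2]

    def test_alarms_increase_with_tracking_noise(self):
        means = []
        for sd in (20.0, 30.0, 40.0):
            profile = OperatorProfile(tracking_noise_sd=sd)
            alarms = [score_performance(
                simulate_session(TaskConfig(condition="low", rng_seed=s), profile),
                TaskConfig(condition="low", rng_seed=s)).n_alarms
                for s in range(100)]
            means.append(np.mean(alarms))
        assert means[0] <= means[1] <= means[2]


def test_behavior_log_jsonl_round_trip(tmp_path, default_profile):
    cfg = TaskConfig(condition="high", rng_seed=9)
    log = simulate_session(cfg, default_profile)
    write_behavior_log(log, tmp_path / "ev.jsonl", tmp_path / "tr.csv")
    back = read_behavior_log(tmp_path / "ev.jsonl", tmp_path / "tr.csv")
    assert back.condition == log.condition
    assert back.meter_events == log.meter_events
    assert back.emergency_events == log.emergency_events
    assert back.numeral_events == log.numeral_events
    assert back.alarm_events == log.alarm_events
    np.testing.assert_allclose(back.tracking_distance_mm, log.tracking_distance_mm,
                               rtol=0, atol=1e-9)
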