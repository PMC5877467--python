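"""Event detectors against constructions, ground truth and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pactkit as pk
from conftest import make_stream


class TestBreaths:
    def test_sinusoid_at_15_per_minute_gives_15_breaths(self):
        t = np.arange(6000) / 100.0
        y = np.sin(2 * np.pi * (15.0 / 60.0) * t)
        det = pk.detect_breaths(make_stream(y), sensor_kind="bioimpedance")
        assert len(det) == 15

    def test_constant_signal_gives_no_breaths(self):
        det = pk.detect_breaths(make_stream(np.full(6000, 3.0)))
        assert len(det) == 0

    def test_empty_stream_gives_empty_log(self):
        det = pk.detect_breaths(make_stream(np.empty(0)))
        assert len(det) == 0

    def test_noisy_hour_recovered_within_two_percent(self, hour_timeline):
        rip = pk.render_rip(hour_timeline, seed=11)
        det = pk.detect_breaths(pk.condition(rip, "rip"))
        truth = len(hour_timeline.breaths)
        assert abs(len(det) - truth) / truth <= 0.02


class TestHeartRate:
    def test_regular_rr_gives_constant_hr(self):
        peaks = pk.EventLog(
            "chest",
            [pk.Event("detected_rpeak", 0.75 * k, 0.75 * k) for k in range(100)],
        )
        _, hr = pk.instantaneous_heart_rate(peaks)
        np.testing.assert_allclose(hr, 80.0, rtol=1e-12)

    def test_window_without_enough_peaks_raises(self):
        # recording starts at the session: the 5-min pre-window holds no peaks
        peaks = pk.EventLog(
            "chest",
            [pk.Event("detected_rpeak", float(k), float(k)) for k in range(100, 200)],
        )
        with pytest.raises(pk.UndefinedStatisticError):
            pk.summarize_heart_rate(peaks, (100.0, 150.0), pre_window_s=300.0)

    def test_summary_windows_do_not_overlap_session(self):
        peaks = pk.EventLog(
            "chest",
            [pk.Event("detected_rpeak", 0.5 * k, 0.5 * k) for k in range(4000)],
        )
        s = pk.summarize_heart_rate(peaks, (800.0, 1000.0))
        assert s.session == (800.0, 1000.0)
        np.testing.assert_allclose(
            [s.smoking_bpm[0], s.pre_bpm[0], s.post_bpm[0]], 120.0, rtol=1e-9
        )


class TestProximity:
    def test_pure_noise_yields_zero_events(self):
        rng = np.random.default_rng(0)
        y = rng.normal(7.31, 1.21, 360_000)
        det = pk.detect_proximity_events(make_stream(y))
        assert len(det) == 0

    def test_single_excursion_yields_one_event_of_right_length(self):
        y = np.full(6000, 7.0)
        y[2000:2200] = 200.0  # 2 s at 100 Hz
        det = pk.detect_proximity_events(make_stream(y))
        assert len(det) == 1
        assert det.events[0].duration_s == pytest.approx(2.0, abs=0.05)

    def test_clean_render_recovers_every_puff(self, hour_timeline):
        s = pk.render_proximity(hour_timeline, noise=pk.NoiseSpec.silent(), seed=0)
        det = pk.detect_proximity_events(pk.condition(s, "proximity"))
        assert len(det) == hour_timeline.n_puffs

    @given(
        threshold_pair=st.tuples(
            st.floats(min_value=15, max_value=300),
            st.floats(min_value=15, max_value=300),
        ),
        seed=st.integers(0, 50),
    )
    def test_raising_threshold_never_increases_count(self, threshold_pair, seed):
        """On proximity-like signals (well-separated unimodal excursions
        over a noise floor) a higher threshold can only drop events."""
        lo, hi = sorted(threshold_pair)
        rng = np.random.default_rng(seed)
        t = np.arange(6000) / 100.0
        y = rng.normal(7.31, 1.21, t.size)
        for k in range(rng.integers(1, 8)):
            center = 5.0 + 7.0 * k + rng.uniform(0, 2)
            amp = rng.uniform(20, 500)
            y += amp * np.exp(-0.5 * ((t - center) / 0.6) ** 2)
        s = make_stream(y)
        n_lo = len(pk.detect_proximity_events(s, pk.DetectionParams(proximity_threshold_mv=lo)))
        n_hi = len(pk.detect_proximity_events(s, pk.DetectionParams(proximity_threshold_mv=hi)))
        assert n_hi <= n_lo


def _oracle_consolidate(presses, sessions, window):
    """Brute-force interval matching: a session counts one cigarette if any
    press starts inside [s0 - window, s1]; unmatched presses are false."""
    n_cig = 0
    matched = set()
    for s0, s1 in sessions:
        hits = [i for i, t in enumerate(presses) if s0 - window <= t <= s1]
        if hits:
            n_cig += 1
        matched.update(hits)
    return n_cig, len(presses) - len(matched)


class TestConsolidateLighter:
    @staticmethod
    def _logs(press_times, session_intervals):
        lighter = pk.EventLog(
            "lighter", [pk.Event("lighter_press", t, t + 0.5) for t in press_times]
        )
        sessions = pk.EventLog(
            "phone",
            [pk.Event("self_report_cigarette", a, b) for a, b in session_intervals],
        )
        return lighter, sessions

    def test_three_presses_before_one_session_give_one_cigarette(self):
        lighter, sessions = self._logs([95.0, 97.0, 99.0], [(100.0, 400.0)])
        res = pk.consolidate_lighter(lighter, sessions)
        assert res.cigarette_count == 1
        assert res.false_presses == 0
        assert res.cigarettes.events[0].attrs["n_presses"] == 3

    def test_uncovered_press_is_a_false_event(self):
        lighter, sessions = self._logs([50.0], [])
        res = pk.consolidate_lighter(lighter, sessions)
        assert res.cigarette_count == 0
        assert res.false_presses == 1

    def test_overlapping_sessions_rejected(self):
        lighter, sessions = self._logs([], [(0.0, 100.0), (50.0, 150.0)])
        with pytest.raises(pk.IntegrityError):
            pk.consolidate_lighter(lighter, sessions)

    @given(
        presses=st.lists(st.floats(min_value=0, max_value=5000), max_size=25),
        starts=st.lists(st.floats(min_value=0, max_value=4500), max_size=6, unique=True),
        seed=st.integers(0, 10),
    )
    def test_matches_brute_force_oracle(self, presses, starts, seed):
        # build disjoint sessions from sorted starts
        sessions = []
        for s in sorted(starts):
            if not sessions or s > sessions[-1][1] + 61.0:
                sessions.append((s, s + 50.0))
        lighter, ses_log = self._logs(presses, sessions)
        res = pk.consolidate_lighter(lighter, ses_log)
        n_cig, n_false = _oracle_consolidate(presses, sessions, 60.0)
        assert res.cigarette_count == n_cig
        assert res.false_presses == n_false
        assert res.grouped_presses + res.false_presses == len(presses)

    def test_conservation_on_simulated_day(self, hour_timeline):
        lighter = pk.render_lighter(hour_timeline, seed=1)
        sessions = pk.render_self_report(hour_timeline)
        res = pk.consolidate_lighter(lighter, sessions)
        assert res.grouped_presses + res.false_presses == len(lighter)
        assert res.cigarette_count <= len(lighter)
        assert res.cigarette_count == len(hour_timeline.cigarettes)
        assert res.false_presses == len(hour_timeline.spurious_lighter_presses)


class TestUsability:
    @staticmethod
    def _screen(timeline):
        rip = pk.render_rip(timeline, seed=3)
        bio = pk.render_bioimpedance(timeline, seed=3, rate_hz=100)
        return pk.screen_usability({"rip": rip, "bioimpedance": bio})

    def test_fully_active_day_fully_usable(self, hour_timeline):
        mask = self._screen(hour_timeline)
        assert mask.usable_percent == pytest.approx(100.0)

    def test_shower_removal_flagged_with_correct_percentage(self):
        cfg = pk.SimConfig(
            seed=13,
            duration_s=7200.0,
            cigarettes_per_day=0.0,
            walk_fraction=0.0,
            removal_intervals=((3600.0, 4500.0),),  # 15-min shower
        )
        tl = pk.simulate_behavior(cfg)
        mask = self._screen(tl)
        assert mask.percent("removed") == pytest.approx(900.0 / 7200.0 * 100.0, abs=2.0)
        assert mask.usable_percent == pytest.approx((7200 - 900) / 7200 * 100.0, abs=2.0)

    def test_labels_agree_with_injected_truth(self):
        cfg = pk.SimConfig(
            seed=17,
            duration_s=7200.0,
            cigarettes_per_day=0.0,
            removal_intervals=((1800.0, 2700.0), (5400.0, 5700.0)),
        )
        tl = pk.simulate_behavior(cfg)
        mask = self._screen(tl)
        minutes = np.arange(0.5, 120.0) * 60.0
        truth = np.array(
            [any(a <= m < b for a, b in cfg.removal_intervals) for m in minutes]
        )
        got = np.array([mask.label_at(m) == "removed" for m in minutes])
        assert (truth == got).mean() >= 0.99


class TestSteps:
    @staticmethod
    def _log():
        events = [
            pk.Event("pedometer_window", 10.0 * k, 10.0 * (k + 1), {"steps": 10})
            for k in range(10)
        ]
        return pk.EventLog("hand", events)

    def test_empty_interval_is_zero(self):
        assert pk.count_steps(self._log(), (50.0, 50.0)) == 0

    def test_fully_covered_windows_sum_exactly(self):
        assert pk.count_steps(self._log(), (0.0, 100.0)) == 100

    def test_straddling_window_prorated(self):
        # covers windows 2..4 fully plus half of window 1 and half of window 5
        assert pk.count_steps(self._log(), (15.0, 55.0)) == 40
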