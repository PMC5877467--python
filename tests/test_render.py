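"""Forward sensor models: physics calibration, noise levels, determinism."""

import numpy as np
import pytest

import pactkit as pk
from pactkit.render import (
    BENCH_RIP_CIRC_CM,
    BENCH_RIP_COUNT,
    proximity_amplitude_mv,
    rpeak_times,
)


@pytest.fixture(scope="module")
def silent():
    return pk.NoiseSpec.silent()


class TestRip:
    @pytest.mark.parametrize("circ, count", list(zip(BENCH_RIP_CIRC_CM, BENCH_RIP_COUNT)))
    def test_calibration_reproduces_bench_counts(self, quiet_timeline, silent, circ, count):
        """Static belt at each bench circumference reproduces the measured
        mean pulse count to within 0.1%."""
        rip = pk.RipParams(baseline_circumference_cm=circ, breath_amplitude_cm=0.0)
        s = pk.render_rip(quiet_timeline, rip=rip, noise=silent, seed=0)
        assert s.data.mean() == pytest.approx(count, rel=1e-3)

    def test_zero_amplitude_zero_noise_is_constant(self, quiet_timeline, silent):
        rip = pk.RipParams(breath_amplitude_cm=0.0)
        s = pk.render_rip(quiet_timeline, rip=rip, noise=silent, seed=0)
        assert np.ptp(s.data) == 0.0

    def test_counts_fall_as_circumference_grows(self, quiet_timeline, silent):
        means = []
        for circ in (60.0, 120.0):
            rip = pk.RipParams(baseline_circumference_cm=circ, breath_amplitude_cm=0.0)
            means.append(pk.render_rip(quiet_timeline, rip=rip, noise=silent).data.mean())
        assert means[1] < means[0]

    def test_inductance_band_and_nyquist(self):
        rip = pk.RipParams()
        circ = np.linspace(60, 120, 50)
        L = rip.inductance_at(circ)
        assert np.all(L >= 2e-6) and np.all(L <= 3e-6)
        assert np.all(rip.frequency_at(circ) < 16e6)

    def test_frequency_cap_violation_raises(self, quiet_timeline, silent):
        hot = pk.RipParams(
            calibration_count=tuple(c * 1.7 for c in BENCH_RIP_COUNT),
            baseline_circumference_cm=60.0,
        )
        with pytest.raises(pk.ModelError):
            pk.render_rip(quiet_timeline, rip=hot, noise=silent)

    def test_render_is_bit_reproducible(self, quiet_timeline):
        a = pk.render_rip(quiet_timeline, seed=9)
        b = pk.render_rip(quiet_timeline, seed=9)
        assert np.array_equal(a.data, b.data)


class TestBioimpedance:
    def test_apnea_segment_is_flat(self, silent):
        tl = pk.BehaviorTimeline(duration_s=30.0)
        s = pk.render_bioimpedance(tl, noise=silent, seed=0, rate_hz=250)
        assert np.ptp(s.data) == 0.0

    def test_breath_peaks_match_truth_within_100ms(self, quiet_timeline, silent):
        s = pk.render_bioimpedance(quiet_timeline, noise=silent, seed=0, rate_hz=250)
        det = pk.detect_breaths(
            pk.condition(s, "bioimpedance"), sensor_kind="bioimpedance"
        )
        truth = np.array([b.peak_time_s for b in quiet_timeline.breaths])
        assert len(det) == len(truth)
        offsets = np.abs(det.starts() - truth)
        assert offsets.max() <= 0.1

    def test_same_truth_as_rip(self, quiet_timeline, silent):
        rip = pk.detect_breaths(
            pk.condition(pk.render_rip(quiet_timeline, noise=silent), "rip")
        )
        bio = pk.detect_breaths(
            pk.condition(
                pk.render_bioimpedance(quiet_timeline, noise=silent, rate_hz=250),
                "bioimpedance",
            ),
            sensor_kind="bioimpedance",
        )
        assert len(rip) == len(bio)


class TestEcg:
    def test_constant_60bpm_one_minute_has_60_rwaves(self, silent):
        tl = pk.BehaviorTimeline(
            duration_s=60.0, hr_knots_s=np.array([0.0, 60.0]), hr_bpm=np.array([60.0, 60.0])
        )
        s = pk.render_ecg(tl, noise=silent, seed=0, mains_amplitude_mv=0.0)
        det = pk.detect_rpeaks(pk.condition(s, "ecg"))
        assert abs(len(det) - 60) <= 1

    def test_zero_interference_config_has_no_mains_line(self, silent):
        tl = pk.BehaviorTimeline(
            duration_s=30.0, hr_knots_s=np.array([0.0, 30.0]), hr_bpm=np.array([70.0, 70.0])
        )
        s = pk.render_ecg(tl, noise=silent, mains_amplitude_mv=0.0, wander_amplitude_mv=0.0)
        spec = np.abs(np.fft.rfft(s.data[:, 0]))
        freqs = np.fft.rfftfreq(len(s), 1.0 / s.sampling_rate_hz)
        line = spec[np.argmin(np.abs(freqs - 60.0))]
        assert line < 0.01 * spec.max()

    def test_rpeaks_recoverable_within_10ms(self, quiet_timeline, silent):
        s = pk.render_ecg(quiet_timeline, noise=silent, seed=0)
        det = pk.detect_rpeaks(pk.condition(s, "ecg"))
        truth = rpeak_times(quiet_timeline)
        assert len(det) == len(truth)
        assert np.abs(det.starts() - truth).max() <= 0.010

    def test_nonpositive_heart_rate_rejected(self):
        with pytest.raises(pk.IntegrityError):
            pk.BehaviorTimeline(
                duration_s=10.0,
                hr_knots_s=np.array([0.0, 10.0]),
                hr_bpm=np.array([0.0, 60.0]),
            )


class TestProximity:
    def test_pure_noise_mean_matches_noise_floor(self):
        tl = pk.BehaviorTimeline(duration_s=600.0)
        s = pk.render_proximity(tl, seed=1)
        assert s.data.mean() == pytest.approx(7.31, abs=0.05)

    def test_puff_at_5cm_exceeds_threshold(self, silent):
        from pactkit.behavior import Cigarette, Puff

        tl = pk.BehaviorTimeline(
            duration_s=60.0,
            cigarettes=[Cigarette(10.0, 50.0, (Puff(30.0, 2.0, 5.0),))],
        )
        s = pk.render_proximity(tl, noise=silent, seed=0)
        t = s.times()
        during = s.data[(t >= 30.0) & (t <= 32.0), 0]
        assert during.min() > 70.0

    def test_amplitude_strictly_decreasing_in_distance(self):
        d = np.linspace(0.0, 40.0, 200)
        a = proximity_amplitude_mv(d)
        assert np.all(np.diff(a) < 0)
        assert proximity_amplitude_mv(11.0) >= 70.0
        assert proximity_amplitude_mv(20.0) < 12.0

    def test_negative_distance_rejected(self):
        with pytest.raises(pk.ModelError):
            proximity_amplitude_mv(-1.0)


class TestImu:
    def test_idle_channel_means_match_bench_noise(self):
        tl = pk.BehaviorTimeline(duration_s=600.0)
        s = pk.render_imu_hand(tl, seed=2)
        for ch in ("ax", "ay", "az"):
            assert s.channel(ch).mean() == pytest.approx(0.19, abs=0.01)
        for ch in ("gx", "gy", "gz"):
            assert s.channel(ch).mean() == pytest.approx(10.0, abs=0.5)

    def test_range_clipping(self, hour_timeline):
        s = pk.render_imu_hand(hour_timeline, gesture_accel_g=50.0, gesture_gyro_dps=5000.0)
        assert np.abs(s.data[:, :3]).max() <= 8.0
        assert np.abs(s.data[:, 3:]).max() <= 2000.0

    def test_chest_accel_stays_in_range(self, hour_timeline):
        s = pk.render_chest_accel(hour_timeline, walk_bounce_g=5.0)
        assert np.abs(s.data).max() <= 2.0

    def test_clean_bump_count_equals_puff_count(self, hour_timeline):
        s = pk.render_imu_hand(hour_timeline, noise=pk.NoiseSpec.silent(), seed=0)
        n = pk.count_h2m_from_imu(pk.condition(s, "imu"))
        assert n == hour_timeline.n_puffs


class TestGpsPedometer:
    def test_stationary_zero_noise_constant_fix(self, quiet_timeline):
        s = pk.render_gps(quiet_timeline, noise=pk.NoiseSpec.silent(), seed=0)
        assert np.ptp(s.channel("latitude_deg")) == 0.0
        assert np.ptp(s.channel("longitude_deg")) == 0.0

    def test_mean_displacement_matches_noise_model(self):
        """At n = 10,000 fixes the mean displacement from the true point
        recovers the configured 15.11 m level within 5%."""
        cfg = pk.SimConfig(seed=6, duration_s=10_000.0, cigarettes_per_day=0.0,
                           walk_fraction=0.0)
        tl = pk.simulate_behavior(cfg)
        s = pk.render_gps(tl, seed=6)
        mean_m, _ = pk.displacement_stats(
            s.channel("latitude_deg"),
            s.channel("longitude_deg"),
            [cfg.start_lat_deg],
            [cfg.start_lon_deg],
        )
        assert mean_m == pytest.approx(15.11, rel=0.05)

    def test_pedometer_window_counts_conserve_truth(self, hour_timeline):
        log = pk.render_pedometer(hour_timeline)
        total = sum(e.attrs["steps"] for e in log.events)
        assert total == hour_timeline.total_steps


class TestClockDrift:
    def test_unit_factor_is_identity(self, hour_timeline):
        log = pk.render_lighter(hour_timeline, seed=0)
        same = pk.apply_clock_drift(log, pk.ClockModel("lighter", 0.0, 1.0))
        assert [e.t_start_s for e in same.events] == [e.t_start_s for e in log.events]

    def test_five_seconds_per_day_offset(self):
        clock = pk.ClockModel("lighter", 0.0, 1.0 + 5.0 / 86400.0)
        log = pk.EventLog("lighter", [pk.Event("lighter_press", 86400.0, 86400.5)])
        drifted = pk.apply_clock_drift(log, clock)
        assert drifted.events[0].t_start_s - 86400.0 == pytest.approx(5.0, abs=1e-9)
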