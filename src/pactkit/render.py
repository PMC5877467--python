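"""Forward models rendering a behavior timeline through every sensor.

Each ``render_*`` function maps the latent :class:`~pactkit.behavior.BehaviorTimeline`
to the raw stream or event log one device would record, including the
idle-bench noise levels and (via :func:`apply_clock_drift`) per-device
clock drift.  All randomness is drawn from a generator seeded with
``(seed, sensor_index)`` so renders are bit-reproducible and mutually
independent.

The respiration belt model is physical: chest circumference modulates the
belt inductance, the LC tank resonates at ``f0 = 1/(2 pi sqrt(L C))``,
and the counter reports ``floor(f0 * 0.01)`` pulses per 10-ms window.
The inductance-versus-circumference curve interpolates the four bench
calibration points (60–120 cm) measured on the simulated-chest rig, which
keeps the belt inside its 2–3 uH band and the oscillator below the 16 MHz
sampling cap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .behavior import PEDOMETER_WINDOW_S, BehaviorTimeline
from .clocksync import ClockModel
from .errors import ModelError
from .logio import Event, EventLog, SensorStream
from .metrics import estimate_inductance, resonant_frequency_hz

__all__ = [
    "RipParams",
    "NoiseSpec",
    "render_rip",
    "render_bioimpedance",
    "render_ecg",
    "render_proximity",
    "render_lighter",
    "render_imu_hand",
    "render_chest_accel",
    "render_gps",
    "render_pedometer",
    "render_self_report",
    "apply_clock_drift",
    "truth_log",
]

# fixed per-sensor substream indices
_SUB = {
    "rip": 1,
    "bioimpedance": 2,
    "ecg": 3,
    "proximity": 4,
    "lighter": 5,
    "imu_hand": 6,
    "chest_accel": 7,
    "gps": 8,
}


def _rng(seed: int, sensor: str) -> np.random.Generator:
    return np.random.default_rng((int(seed), _SUB[sensor]))


# Bench calibration of the respiration belt: mean pulse count per 10-ms
# window at four simulated chest circumferences on the wooden-rig test.
BENCH_RIP_CIRC_CM = (60.0, 80.0, 100.0, 120.0)
BENCH_RIP_COUNT = (102_376.76, 96_199.76, 92_954.09, 89_088.46)
SAMPLING_CAP_HZ = 16e6  # half the 32 MHz system clock (Nyquist)


@dataclass(frozen=True)
class RipParams:
    """Physical parameters of the inductance-belt oscillator.

    ``c_eq_farads`` is the equivalent capacitance of the two 220 pF series
    capacitors.  The belt inductance is obtained by monotone piecewise-linear
    interpolation of the bench calibration points (circumference in cm
    against the inductance implied by each measured pulse count), linearly
    extrapolated outside 60–120 cm.
    """

    c_eq_farads: float = 110e-12
    count_window_s: float = 0.01
    baseline_circumference_cm: float = 85.63  # study-population mean chest size
    breath_amplitude_cm: float = 1.5
    calibration_circ_cm: tuple = BENCH_RIP_CIRC_CM
    calibration_count: tuple = BENCH_RIP_COUNT

    def calibration_inductance_h(self) -> np.ndarray:
        """Inductance at each calibration circumference, from inverting the
        resonance formula on the measured counts."""
        f0 = np.asarray(self.calibration_count) / self.count_window_s
        return np.array([estimate_inductance(f, self.c_eq_farads) for f in f0])

    def inductance_at(self, circumference_cm) -> np.ndarray:
        """Belt inductance (H) at the given chest circumference(s)."""
        c = np.asarray(circumference_cm, dtype=float)
        xs = np.asarray(self.calibration_circ_cm)
        ys = self.calibration_inductance_h()
        out = np.interp(c, xs, ys)
        # linear extrapolation beyond the calibrated range
        lo = c < xs[0]
        hi = c > xs[-1]
        if np.any(lo):
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out = np.where(lo, ys[0] + slope * (c - xs[0]), out)
        if np.any(hi):
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out = np.where(hi, ys[-1] + slope * (c - xs[-1]), out)
        return out

    def fit_affine_inductance(self) -> tuple[float, float]:
        """Least-squares affine law ``L = l0 + slope * circumference`` over
        the calibration points, for linearity analyses."""
        slope, l0 = np.polyfit(
            np.asarray(self.calibration_circ_cm), self.calibration_inductance_h(), 1
        )
        return float(l0), float(slope)

    def frequency_at(self, circumference_cm) -> np.ndarray:
        L = self.inductance_at(circumference_cm)
        return 1.0 / (2.0 * np.pi * np.sqrt(L * self.c_eq_farads))


@dataclass(frozen=True)
class NoiseSpec:
    """Idle-bench noise model per sensor, (mean, sd) pairs in the sensor's
    native unit.  Defaults are the bench characterization values."""

    hand_accel_g: tuple[float, float] = (0.19, 0.00324)
    hand_gyro_dps: tuple[float, float] = (10.0, 1.57)
    chest_accel_g: tuple[float, float] = (0.04, 0.00416)
    rip_count: tuple[float, float] = (5.23, 1.29)
    bioimpedance_mv: tuple[float, float] = (0.0, 0.0)
    ecg_mv: tuple[float, float] = (0.007, 0.003)
    proximity_mv: tuple[float, float] = (7.31, 1.21)
    gps_displacement_m: tuple[float, float] = (15.11, 2.639)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _, sd = getattr(self, name)
            if sd < 0:
                raise ModelError(f"negative noise sd for {name}")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All-zero noise, for clean-render ground-truth checks."""
        return cls(
            hand_accel_g=(0.0, 0.0),
            hand_gyro_dps=(0.0, 0.0),
            chest_accel_g=(0.0, 0.0),
            rip_count=(0.0, 0.0),
            bioimpedance_mv=(0.0, 0.0),
            ecg_mv=(0.0, 0.0),
            proximity_mv=(0.0, 0.0),
            gps_displacement_m=(0.0, 0.0),
        )


def _draw(rng, noise_pair: tuple[float, float], n: int) -> np.ndarray:
    mean, sd = noise_pair
    if sd == 0.0:
        return np.full(n, mean)
    return rng.normal(mean, sd, n)


def _window(timeline: BehaviorTimeline, t_start_s, t_end_s):
    t0 = 0.0 if t_start_s is None else float(t_start_s)
    t1 = timeline.duration_s if t_end_s is None else float(t_end_s)
    if t1 < t0:
        raise ModelError("render window ends before it starts")
    return t0, t1


def _breath_bump(t: np.ndarray, peak_s: float, width_s: float) -> np.ndarray:
    """Raised-cosine bump of unit height centred on the breath peak."""
    x = (t - peak_s) / (width_s / 2.0)
    out = np.zeros_like(t)
    m = np.abs(x) < 1.0
    out[m] = 0.5 * (1.0 + np.cos(np.pi * x[m]))
    return out


def _add_breaths(t: np.ndarray, rate_hz: float, timeline: BehaviorTimeline,
                 amplitude: float) -> np.ndarray:
    """Sum of per-breath bumps on the sample grid; smoke inhalations are
    deeper and longer than tidal breaths."""
    y = np.zeros_like(t)
    if not len(t):
        return y
    t0 = t[0]
    n = len(t)
    for br in timeline.breaths:
        width = 2.5 + 1.5 * br.depth_fraction
        i0 = max(0, int((br.peak_time_s - width / 2 - t0) * rate_hz))
        i1 = min(n, int((br.peak_time_s + width / 2 - t0) * rate_hz) + 2)
        if i1 <= i0:
            continue
        y[i0:i1] += amplitude * br.depth_fraction * _breath_bump(t[i0:i1], br.peak_time_s, width)
    # device off-body: no breathing modulation reaches the sensor
    for a, b in timeline.removal_intervals:
        y[(t >= a) & (t < b)] = 0.0
    return y


# ---------------------------------------------------------------------------
# respiration

def render_rip(
    timeline: BehaviorTimeline,
    rip: RipParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """Pulse-count stream of the inductance-belt oscillator at 100 Hz.

    Chest circumference is the baseline plus the breath modulation
    (inhalation expands the chest, lowering the oscillator frequency, so
    counts fall as circumference grows).  Each 10-ms window reports
    ``floor(f0 * window)`` plus the idle-noise draw, as integer counts.
    """
    rip = rip or RipParams()
    noise = noise or NoiseSpec()
    rng = _rng(seed, "rip")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    t = t0 + np.arange(int(round((t1 - t0) * rate_hz))) / rate_hz
    circ = rip.baseline_circumference_cm + _add_breaths(
        t, rate_hz, timeline, rip.breath_amplitude_cm
    )
    f0 = rip.frequency_at(circ)
    if np.any(f0 >= SAMPLING_CAP_HZ):
        raise ModelError("implied resonant frequency reaches the 16 MHz sampling cap")
    counts = np.floor(f0 * rip.count_window_s) + np.round(_draw(rng, noise.rip_count, len(t)))
    return SensorStream("chest", ["pulse_count"], ["count"], rate_hz, t0, counts)


def render_bioimpedance(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 1000.0,
    amplitude_mv: float = 5.0,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """Thoracic-impedance respiration waveform (mV) at 1 kHz.

    Shares breath peak times with the inductance belt (same ground truth);
    amplitude scaling is arbitrary.  Chest expansion raises impedance, so
    breath peaks are signal maxima.
    """
    noise = noise or NoiseSpec()
    rng = _rng(seed, "bioimpedance")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    t = t0 + np.arange(int(round((t1 - t0) * rate_hz))) / rate_hz
    y = _add_breaths(t, rate_hz, timeline, amplitude_mv)
    y = y + _draw(rng, noise.bioimpedance_mv, len(t))
    return SensorStream("chest", ["bioimpedance"], ["mV"], rate_hz, t0, y)


# ---------------------------------------------------------------------------
# ECG

def rpeak_times(timeline: BehaviorTimeline,
                t_start_s: float | None = None,
                t_end_s: float | None = None) -> np.ndarray:
    """Ground-truth R-peak times implied by the heart-rate profile.

    Successive R–R intervals integrate the instantaneous rate:
    ``t_{k+1} = t_k + 60 / hr(t_k)``.
    """
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    if np.any(np.asarray(timeline.hr_bpm) <= 0):
        raise ModelError("heart-rate profile must be positive")
    times = []
    t = t0 + 0.3
    while t < t1:
        times.append(t)
        t += 60.0 / float(timeline.hr_at(t))
    return np.asarray(times)


def render_ecg(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 1000.0,
    r_amplitude_mv: float = 1.0,
    qrs_sigma_s: float = 0.008,
    mains_amplitude_mv: float = 0.05,
    mains_hz: float = 60.0,
    wander_amplitude_mv: float = 0.1,
    wander_hz: float = 0.25,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """Stylized Lead-I ECG (mV) at 1 kHz: a Gaussian QRS impulse train with
    R–R intervals from the heart-rate profile, additive power-line
    interference, slow baseline wander, and idle noise."""
    noise = noise or NoiseSpec()
    rng = _rng(seed, "ecg")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    n = int(round((t1 - t0) * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    y = np.zeros(n)
    half = 5.0 * qrs_sigma_s
    for tr in rpeak_times(timeline, t0, t1):
        i0 = max(0, int((tr - half - t0) * rate_hz))
        i1 = min(n, int((tr + half - t0) * rate_hz) + 2)
        if i1 <= i0:
            continue
        y[i0:i1] += r_amplitude_mv * np.exp(-0.5 * ((t[i0:i1] - tr) / qrs_sigma_s) ** 2)
    if mains_amplitude_mv:
        y += mains_amplitude_mv * np.sin(2 * np.pi * mains_hz * t)
    if wander_amplitude_mv:
        y += wander_amplitude_mv * np.sin(2 * np.pi * wander_hz * t)
    y += _draw(rng, noise.ecg_mv, n)
    return SensorStream("chest", ["ecg"], ["mV"], rate_hz, t0, y)


# ---------------------------------------------------------------------------
# RF proximity

PROX_FULL_SCALE_MV = 2800.0  # receiver full range near contact
PROX_EFOLD_CM = 3.5  # decay length calibrated so 11 cm still clears 70 mV


def proximity_amplitude_mv(distance_cm) -> np.ndarray:
    """Received signal strength versus Tx–Rx distance.

    Exponential-decay calibration: ~2.8 V near contact, >= 10x the 7 mV
    noise mean at 11 cm, indistinguishable from the noise floor beyond
    ~20 cm.  Strictly decreasing in distance.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ModelError("Tx–Rx distance cannot be negative")
    return PROX_FULL_SCALE_MV * np.exp(-d / PROX_EFOLD_CM)


def render_proximity(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
    out_of_reach_cm: float = 60.0,
    approach_s: float = 0.5,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """RF receiver output (mV) at 100 Hz.

    Outside puffs the wrist transmitter is out of reach and only the
    noise floor is recorded; during each puff the distance ramps from
    out-of-reach down to the puff's Tx–Rx distance, holds for the
    inhalation, and ramps back."""
    noise = noise or NoiseSpec()
    rng = _rng(seed, "proximity")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    n = int(round((t1 - t0) * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    dist = np.full(n, out_of_reach_cm)
    for cig in timeline.cigarettes:
        for p in cig.puffs:
            a, b = p.t_s, p.t_s + p.duration_s
            i0 = max(0, int((a - approach_s - t0) * rate_hz))
            i1 = min(n, int((b + approach_s - t0) * rate_hz) + 1)
            if i1 <= i0:
                continue
            seg = t[i0:i1]
            d = np.full(len(seg), p.tx_rx_distance_cm)
            ramp_in = seg < a
            ramp_out = seg > b
            d[ramp_in] = p.tx_rx_distance_cm + (out_of_reach_cm - p.tx_rx_distance_cm) * (
                (a - seg[ramp_in]) / approach_s
            )
            d[ramp_out] = p.tx_rx_distance_cm + (out_of_reach_cm - p.tx_rx_distance_cm) * (
                (seg[ramp_out] - b) / approach_s
            )
            dist[i0:i1] = np.minimum(dist[i0:i1], d)
    y = proximity_amplitude_mv(dist) + _draw(rng, noise.proximity_mv, n)
    return SensorStream("chest", ["proximity"], ["mV"], rate_hz, t0, y)


# ---------------------------------------------------------------------------
# lighter and self-report logs

def render_lighter(
    timeline: BehaviorTimeline,
    seed: int = 0,
    presses_range: tuple[int, int] = (1, 3),
    press_duration_s: float = 0.8,
    press_spacing_s: float = 2.0,
) -> EventLog:
    """Instrumented-lighter press/release log.

    Each cigarette gets one to a few rapid presses ending at the lighting
    time (repeated strikes before the cigarette catches); spurious presses
    occur outside smoking sessions."""
    rng = _rng(seed, "lighter")
    events = []
    for cig in timeline.cigarettes:
        n = int(rng.integers(presses_range[0], presses_range[1] + 1))
        for k in range(n):
            start = cig.t_light_s - (n - 1 - k) * press_spacing_s
            events.append(
                Event("lighter_press", start, start + press_duration_s, {"spurious": False})
            )
    for t_sp in timeline.spurious_lighter_presses:
        events.append(
            Event("lighter_press", t_sp, t_sp + press_duration_s, {"spurious": True})
        )
    return EventLog("lighter", events)


def render_self_report(timeline: BehaviorTimeline) -> EventLog:
    """Smartphone self-report log: one interval per smoked cigarette."""
    events = [
        Event("self_report_cigarette", c.t_light_s, c.t_end_s, {})
        for c in timeline.cigarettes
    ]
    return EventLog("phone", events)


# ---------------------------------------------------------------------------
# inertial sensors

HAND_ACCEL_RANGE_G = 8.0
HAND_GYRO_RANGE_DPS = 2000.0
CHEST_ACCEL_RANGE_G = 2.0


def _gesture_bumps(t: np.ndarray, rate_hz: float, centers, widths, amplitude) -> np.ndarray:
    y = np.zeros_like(t)
    if not len(t):
        return y
    t0 = t[0]
    n = len(t)
    for c, w in zip(centers, widths):
        i0 = max(0, int((c - w / 2 - t0) * rate_hz))
        i1 = min(n, int((c + w / 2 - t0) * rate_hz) + 2)
        if i1 <= i0:
            continue
        y[i0:i1] += amplitude * _breath_bump(t[i0:i1], c, w)
    return y


def render_imu_hand(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
    gesture_accel_g: float = 1.5,
    gesture_gyro_dps: float = 90.0,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """Wrist 6-axis IMU stream (ax, ay, az in g; gx, gy, gz in dps).

    A hand-to-mouth gesture bump surrounds every puff; values clip at the
    configured +-8 g / 2000 dps ranges."""
    noise = noise or NoiseSpec()
    rng = _rng(seed, "imu_hand")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    n = int(round((t1 - t0) * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    puffs = [p for c in timeline.cigarettes for p in c.puffs]
    centers = [p.t_s for p in puffs]
    widths = [p.duration_s + 1.0 for p in puffs]
    accel_bump = _gesture_bumps(t, rate_hz, centers, widths, gesture_accel_g)
    gyro_bump = _gesture_bumps(t, rate_hz, centers, widths, gesture_gyro_dps)
    data = np.empty((n, 6))
    for j in range(3):
        data[:, j] = _draw(rng, noise.hand_accel_g, n)
    for j in range(3, 6):
        data[:, j] = _draw(rng, noise.hand_gyro_dps, n)
    data[:, 0] += accel_bump  # gesture dominates the x axis
    data[:, 3] += gyro_bump
    data[:, :3] = np.clip(data[:, :3], -HAND_ACCEL_RANGE_G, HAND_ACCEL_RANGE_G)
    data[:, 3:] = np.clip(data[:, 3:], -HAND_GYRO_RANGE_DPS, HAND_GYRO_RANGE_DPS)
    return SensorStream(
        "hand",
        ["ax", "ay", "az", "gx", "gy", "gz"],
        ["g", "g", "g", "dps", "dps", "dps"],
        rate_hz,
        t0,
        data,
    )


def render_chest_accel(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 100.0,
    walk_bounce_g: float = 0.3,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> SensorStream:
    """Chest three-axis accelerometer (g) with walking bounce at the step
    cadence during walking segments; clips at +-2 g."""
    noise = noise or NoiseSpec()
    rng = _rng(seed, "chest_accel")
    t0, t1 = _window(timeline, t_start_s, t_end_s)
    n = int(round((t1 - t0) * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    data = np.empty((n, 3))
    for j in range(3):
        data[:, j] = _draw(rng, noise.chest_accel_g, n)
    walk = np.zeros(n, dtype=bool)
    for a, b, lab in timeline.activities:
        if "walk" in lab:
            i0 = max(0, int((a - t0) * rate_hz))
            i1 = min(n, int((b - t0) * rate_hz))
            walk[i0:i1] = True
    data[walk, 2] += walk_bounce_g * np.sin(2 * np.pi * 1.75 * t[walk])
    data = np.clip(data, -CHEST_ACCEL_RANGE_G, CHEST_ACCEL_RANGE_G)
    return SensorStream("chest", ["cx", "cy", "cz"], ["g", "g", "g"], rate_hz, t0, data)


# ---------------------------------------------------------------------------
# GPS and pedometer

def render_gps(
    timeline: BehaviorTimeline,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = 1.0,
) -> SensorStream:
    """GPS fixes (WGS-84 decimal degrees) at 1 Hz.

    Each outdoor fix is the true route point displaced by a draw of the
    coordinate-displacement noise (magnitude ~ N(mean, sd), random
    bearing).  Indoors the receiver loses the satellites and keeps
    logging its last outdoor fix."""
    noise = noise or NoiseSpec()
    rng = _rng(seed, "gps")
    t = timeline.route_t_s
    n = len(t)
    if n == 0:
        return SensorStream(
            "chest", ["latitude_deg", "longitude_deg"], ["degrees", "degrees"],
            rate_hz, 0.0, np.empty((0, 2)),
        )
    mag = np.clip(_draw(rng, noise.gps_displacement_m, n), 0.0, None)
    bearing = rng.uniform(0.0, 2 * np.pi, n)
    m_per_deg_lat = 111_195.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(timeline.route_lat_deg))
    lat = timeline.route_lat_deg + mag * np.cos(bearing) / m_per_deg_lat
    lon = timeline.route_lon_deg + mag * np.sin(bearing) / m_per_deg_lon
    for (a, b) in timeline.indoor_intervals:
        i0, i1 = np.searchsorted(t, [a, b])
        if i0 >= n:
            continue
        hold = max(i0 - 1, 0) if i0 > 0 else None
        if hold is None:
            continue  # recording starts indoors: first fix stands
        lat[i0:i1] = lat[hold]
        lon[i0:i1] = lon[hold]
    return SensorStream(
        "chest",
        ["latitude_deg", "longitude_deg"],
        ["degrees", "degrees"],
        rate_hz,
        float(t[0]),
        np.column_stack([lat, lon]),
    )


def render_pedometer(timeline: BehaviorTimeline) -> EventLog:
    """Pedometer log: one event per 13.63-s buffer window with the step
    count in the ``steps`` attribute.  Windows tile the recording, so the
    attribute sum conserves the ground-truth total."""
    events = [
        Event(
            "pedometer_window",
            w0,
            min(w0 + PEDOMETER_WINDOW_S, timeline.duration_s),
            {"steps": int(count)},
        )
        for w0, count in timeline.steps
    ]
    return EventLog("hand", events)


# ---------------------------------------------------------------------------
# clock drift

def apply_clock_drift(obj, clock: ClockModel):
    """Re-express a stream or event log on its drifting device clock.

    Raw timestamps follow ``t = t0 + f * (t_true - t0)``; this is the
    exact inverse of the linear compensation, so
    ``compensate(apply_clock_drift(x)) == x`` to numeric tolerance.
    """
    if not clock.f > 0:
        raise ModelError("clock factor must be positive")
    if isinstance(obj, SensorStream):
        return replace(
            obj,
            start_time_s=clock.t0_s + clock.f * (obj.start_time_s - clock.t0_s),
            sampling_rate_hz=obj.sampling_rate_hz / clock.f,
        )
    if isinstance(obj, EventLog):
        events = [
            Event(
                e.kind,
                clock.t0_s + clock.f * (e.t_start_s - clock.t0_s),
                clock.t0_s + clock.f * (e.t_end_s - clock.t0_s),
                dict(e.attrs),
            )
            for e in obj.events
        ]
        return EventLog(obj.device_id, events)
    raise TypeError(f"cannot apply clock drift to {type(obj).__name__}")


def truth_log(timeline: BehaviorTimeline) -> EventLog:
    """Ground-truth event log (breaths, puffs, removals) for scoring
    detectors against the simulation."""
    events = [
        Event("breath_truth", b.peak_time_s, b.peak_time_s, {"depth": b.depth_fraction})
        for b in timeline.breaths
    ]
    for c in timeline.cigarettes:
        for p in c.puffs:
            events.append(
                Event("puff_truth", p.t_s, p.t_s + p.duration_s,
                      {"distance_cm": p.tx_rx_distance_cm})
            )
    for a, b in timeline.removal_intervals:
        events.append(Event("removal_truth", a, b, {}))
    return EventLog("truth", events)
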