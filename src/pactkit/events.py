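"""Reduction of conditioned streams and raw logs to behavioral events.

Breaths and R-waves are local maxima of the conditioned respiration and
ECG signals; hand-to-mouth proximity events are threshold excursions of
the RF receiver voltage (threshold ten times the mean noise amplitude);
cigarette counts come from consolidating lighter presses against smoking
sessions; usability screening flags flat-line (device-off) segments
before any counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import IntegrityError, UndefinedStatisticError
from .logio import Event, EventLog, SensorStream, UsabilityMask

__all__ = [
    "DetectionParams",
    "HeartRateSummary",
    "detect_breaths",
    "detect_rpeaks",
    "instantaneous_heart_rate",
    "summarize_heart_rate",
    "detect_proximity_events",
    "ConsolidationResult",
    "consolidate_lighter",
    "screen_usability",
    "count_steps",
    "count_h2m_from_imu",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detector thresholds and windows.

    ``proximity_threshold_mv`` defaults to ten times the ~7 mV mean noise
    amplitude of the RF receiver; use :meth:`from_noise_mean` to derive it
    from a different noise floor.
    """

    proximity_threshold_mv: float = 70.0
    min_breath_interval_s: float = 1.0  # caps breathing at 60/min
    # high-pass rebound between widely spaced breaths reaches ~10% of the
    # signal IQR; true breaths exceed 100%, so 20% separates them cleanly
    min_breath_prominence: float = 0.20  # fraction of the signal IQR
    min_rr_interval_s: float = 0.3  # caps heart rate at 200 bpm
    rpeak_prominence_frac: float = 0.4  # fraction of the 99.9th amplitude percentile
    lighter_merge_window_s: float = 60.0
    proximity_merge_gap_s: float = 0.5
    flatline_window_s: float = 60.0
    flatline_sd_floor: dict = field(
        default_factory=lambda: {"rip": 3 * 1.29, "bioimpedance": 1e-3}
    )
    imu_gesture_threshold: float = 0.75  # g above the channel median
    imu_min_gap_s: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "proximity_threshold_mv",
            "min_breath_interval_s",
            "min_breath_prominence",
            "min_rr_interval_s",
            "lighter_merge_window_s",
            "proximity_merge_gap_s",
            "flatline_window_s",
        ):
            if getattr(self, name) <= 0:
                raise IntegrityError(f"{name} must be positive")

    @classmethod
    def from_noise_mean(cls, noise_mean_mv: float, **kw) -> "DetectionParams":
        """Threshold rule: ten times the mean noise amplitude."""
        return cls(proximity_threshold_mv=10.0 * noise_mean_mv, **kw)


# ---------------------------------------------------------------------------
# respiration

def detect_breaths(
    stream: SensorStream,
    params: DetectionParams | None = None,
    sensor_kind: str = "rip",
) -> EventLog:
    """Count breaths as accepted local maxima of the conditioned
    respiration signal.

    The inductance-belt pulse count *falls* during inhalation (chest
    expansion lowers the oscillator frequency), so for ``sensor_kind="rip"``
    maxima are found on the negated signal; the impedance waveform rises
    with expansion and is used as-is.  Maxima closer than
    ``min_breath_interval_s`` or with prominence below
    ``min_breath_prominence`` times the signal IQR are rejected.
    """
    params = params or DetectionParams()
    if len(stream) == 0:
        return EventLog(stream.device_id, [])
    y = stream.data[:, 0].astype(float)
    if sensor_kind == "rip":
        y = -y
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    if iqr == 0.0:
        return EventLog(stream.device_id, [])
    distance = max(1, int(round(params.min_breath_interval_s * stream.sampling_rate_hz)))
    peaks, _ = _signal.find_peaks(
        y, distance=distance, prominence=params.min_breath_prominence * iqr
    )
    t = stream.times()
    events = [Event("detected_breath", float(t[i]), float(t[i]), {}) for i in peaks]
    return EventLog(stream.device_id, events)


# ---------------------------------------------------------------------------
# ECG

def detect_rpeaks(stream: SensorStream, params: DetectionParams | None = None) -> EventLog:
    """Locate R-waves as prominent local maxima of the de-noised ECG."""
    params = params or DetectionParams()
    if len(stream) == 0:
        return EventLog(stream.device_id, [])
    y = stream.data[:, 0].astype(float)
    scale = float(np.percentile(np.abs(y), 99.9))
    if scale == 0.0:
        return EventLog(stream.device_id, [])
    distance = max(1, int(round(params.min_rr_interval_s * stream.sampling_rate_hz)))
    peaks, _ = _signal.find_peaks(
        y, distance=distance, prominence=params.rpeak_prominence_frac * scale
    )
    t = stream.times()
    events = [Event("detected_rpeak", float(t[i]), float(t[i]), {}) for i in peaks]
    return EventLog(stream.device_id, events)


def instantaneous_heart_rate(rpeaks: EventLog) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous heart rate, 60 / RR seconds, at each RR midpoint."""
    t = rpeaks.starts()
    if len(t) < 2:
        raise UndefinedStatisticError("need at least two R-peaks for a heart rate")
    rr = np.diff(t)
    return (t[:-1] + t[1:]) / 2.0, 60.0 / rr


@dataclass(frozen=True)
class HeartRateSummary:
    """Mean +- sd heart rate during a smoking session, the 5 min before it
    and the 15 min after it (windows never overlap the session)."""

    smoking_bpm: tuple[float, float]
    pre_bpm: tuple[float, float]
    post_bpm: tuple[float, float]
    session: tuple[float, float]
    pre_window_s: float = 300.0
    post_window_s: float = 900.0

    def to_dict(self) -> dict:
        return {
            "smoking_bpm": list(self.smoking_bpm),
            "pre_bpm": list(self.pre_bpm),
            "post_bpm": list(self.post_bpm),
            "session": list(self.session),
        }


def _window_hr(mid: np.ndarray, hr: np.ndarray, t0: float, t1: float) -> tuple[float, float]:
    m = (mid >= t0) & (mid <= t1)
    if m.sum() < 2:
        raise UndefinedStatisticError(
            f"fewer than two heart-rate samples in window [{t0}, {t1}]"
        )
    return float(hr[m].mean()), float(hr[m].std(ddof=0))


def summarize_heart_rate(
    rpeaks: EventLog,
    session: tuple[float, float],
    pre_window_s: float = 300.0,
    post_window_s: float = 900.0,
) -> HeartRateSummary:
    """Average the instantaneous heart rate over the session, the window
    before lighting and the window after the session end.

    Raises
    ------
    UndefinedStatisticError
        If any window holds fewer than two R-peaks (no silent zero).
    """
    t0, t1 = session
    if t1 <= t0:
        raise IntegrityError("session ends before it starts")
    mid, hr = instantaneous_heart_rate(rpeaks)
    return HeartRateSummary(
        smoking_bpm=_window_hr(mid, hr, t0, t1),
        pre_bpm=_window_hr(mid, hr, t0 - pre_window_s, t0),
        post_bpm=_window_hr(mid, hr, t1, t1 + post_window_s),
        session=(t0, t1),
        pre_window_s=pre_window_s,
        post_window_s=post_window_s,
    )


# ---------------------------------------------------------------------------
# RF proximity

def detect_proximity_events(
    stream: SensorStream, params: DetectionParams | None = None
) -> EventLog:
    """Hand-to-mouth proximity events: maximal runs of samples whose
    amplitude exceeds the threshold, with runs separated by less than
    ``proximity_merge_gap_s`` merged into one event."""
    params = params or DetectionParams()
    if len(stream) == 0:
        return EventLog(stream.device_id, [])
    y = stream.data[:, 0]
    above = y > params.proximity_threshold_mv
    if not above.any():
        return EventLog(stream.device_id, [])
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])
    t = stream.times()
    gap = params.proximity_merge_gap_s
    merged: list[list[float]] = []
    for i0, i1 in zip(run_starts, run_ends):
        a, b = float(t[i0]), float(t[i1])
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = [
        Event("detected_proximity", a, b, {"peak_mv": float(y[(t >= a) & (t <= b)].max())})
        for a, b in merged
    ]
    return EventLog(stream.device_id, events)


# ---------------------------------------------------------------------------
# lighter consolidation

@dataclass(frozen=True)
class ConsolidationResult:
    """Outcome of grouping lighter presses into cigarettes.

    Conservation holds: ``grouped_presses + false_presses`` equals the raw
    press count.
    """

    cigarettes: EventLog
    false_presses: int
    grouped_presses: int

    @property
    def cigarette_count(self) -> int:
        return len(self.cigarettes)


def consolidate_lighter(
    lighter: EventLog,
    sessions: EventLog,
    params: DetectionParams | None = None,
) -> ConsolidationResult:
    """Group lighter presses into cigarette estimates against smoking
    sessions (self-reported or detected).

    A press belongs to a session if it starts inside it or within
    ``lighter_merge_window_s`` before the session start; each session with
    at least one press yields one cigarette estimate (multiple consecutive
    strikes count once).  Presses covered by no session are discarded and
    reported as false lighting events.

    Raises
    ------
    IntegrityError
        If the session intervals overlap.
    """
    params = params or DetectionParams()
    ses = [
        (e.t_start_s, e.t_end_s)
        for e in sessions.events
        if e.kind in ("self_report_cigarette", "cigarette_estimate")
    ]
    for (a0, a1), (b0, b1) in zip(ses, ses[1:]):
        if b0 < a1:
            raise IntegrityError("overlapping smoking sessions")
    presses = [e for e in lighter.events if e.kind == "lighter_press"]
    w = params.lighter_merge_window_s
    per_session = [0] * len(ses)
    false_presses = 0
    for e in presses:
        hit = None
        for k, (s0, s1) in enumerate(ses):
            if s0 - w <= e.t_start_s <= s1:
                hit = k
                break
        if hit is None:
            false_presses += 1
        else:
            per_session[hit] += 1
    events = [
        Event("cigarette_estimate", s0, s1, {"n_presses": n})
        for (s0, s1), n in zip(ses, per_session)
        if n > 0
    ]
    grouped = sum(per_session)
    return ConsolidationResult(
        cigarettes=EventLog(lighter.device_id, events),
        false_presses=false_presses,
        grouped_presses=grouped,
    )


# ---------------------------------------------------------------------------
# usability screening

def screen_usability(
    respiration_streams: dict[str, SensorStream],
    params: DetectionParams | None = None,
) -> UsabilityMask:
    """Label the recording usable / removed / ambiguous from flat-line
    screening of the respiration channels.

    The recording is tiled with ``flatline_window_s`` windows; a window
    where every respiration sensor's standard deviation sits below its
    floor is ``removed`` (device off-body), a window where the sensors
    disagree (breathing visible on one but not the other) is
    ``ambiguous``, anything else ``usable``.
    """
    params = params or DetectionParams()
    if not respiration_streams:
        raise IntegrityError("need at least one respiration stream")
    t0 = max(s.start_time_s for s in respiration_streams.values())
    t1 = min(s.start_time_s + s.duration_s for s in respiration_streams.values())
    if t1 <= t0:
        raise IntegrityError("streams do not overlap in time")
    w = params.flatline_window_s
    n_win = max(1, int(np.ceil((t1 - t0) / w)))
    labels = []
    for k in range(n_win):
        a = t0 + k * w
        b = min(a + w, t1)
        states = []
        for kind, s in respiration_streams.items():
            i0 = int(round((a - s.start_time_s) * s.sampling_rate_hz))
            i1 = int(round((b - s.start_time_s) * s.sampling_rate_hz))
            seg = s.data[max(i0, 0) : max(i1, 0), 0]
            floor = params.flatline_sd_floor.get(kind, 1e-9)
            states.append(bool(seg.size) and float(seg.std()) >= floor)
        if all(states):
            labels.append("usable")
        elif not any(states):
            labels.append("removed")
        else:
            labels.append("ambiguous")
    segments: list[tuple[float, float, str]] = []
    for k, lab in enumerate(labels):
        a = t0 + k * w
        b = min(a + w, t1)
        if segments and segments[-1][2] == lab:
            segments[-1] = (segments[-1][0], b, lab)
        else:
            segments.append((a, b, lab))
    return UsabilityMask(segments)


# ---------------------------------------------------------------------------
# pedometer and IMU counts

def count_steps(pedometer: EventLog, interval: tuple[float, float]) -> int:
    """Steps inside *interval*: buffer-window counts summed, windows that
    straddle the interval boundary prorated by their overlap fraction."""
    a, b = interval
    if b <= a:
        return 0
    total = 0.0
    for e in pedometer.events:
        if e.kind != "pedometer_window":
            continue
        overlap = min(b, e.t_end_s) - max(a, e.t_start_s)
        if overlap <= 0 or e.duration_s == 0:
            continue
        total += e.attrs.get("steps", 0) * min(1.0, overlap / e.duration_s)
    return int(round(total))


def _default_imu_detector(stream: SensorStream, params: DetectionParams) -> int:
    """Documented placeholder gesture counter: prominent threshold
    crossings of the dominant low-passed accelerometer channel.  It is a
    stand-in for a trained hand-to-mouth gesture classifier, adequate for
    clean synthetic renders only."""
    y = stream.channel("ax") if "ax" in stream.channels else stream.data[:, 0]
    y = y - np.median(y)
    distance = max(1, int(round(params.imu_min_gap_s * stream.sampling_rate_hz)))
    peaks, _ = _signal.find_peaks(y, height=params.imu_gesture_threshold, distance=distance)
    return int(len(peaks))


def count_h2m_from_imu(
    stream: SensorStream,
    params: DetectionParams | None = None,
    detector=None,
) -> int:
    """Count hand-to-mouth gestures in a conditioned wrist-IMU stream.

    The gesture classifier is pluggable: pass ``detector(stream) -> int``
    to substitute a trained model.  The default is a simple
    threshold-crossing placeholder (see :func:`_default_imu_detector`).
    """
    params = params or DetectionParams()
    if detector is not None:
        return int(detector(stream))
    return _default_imu_detector(stream, params)
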