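"""Ground-truth smoker-behavior generator.

The simulator produces a :class:`BehaviorTimeline` — the latent truth a
wearable sensor suite observes: breath peak times, cigarettes with their
individual puffs (each puff a hand-to-mouth approach of the wrist
transmitter to within a few centimetres of the chest receiver), spurious
lighter presses, step counts per pedometer buffer window, a heart-rate
profile that rises during smoking and relaxes back to baseline within
about fifteen minutes, and a walking route.

Defaults mirror the free-living study conditions: roughly eleven
cigarettes per day, breathing between 12 and 20 breaths/min at rest, a
sitting–smoking heart rate near 112 bpm over a pre-smoking baseline near
82 bpm, and per-device clock drift of a few seconds per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, IntegrityError

__all__ = ["Puff", "Cigarette", "Breath", "BehaviorTimeline", "SimConfig", "simulate_behavior"]


@dataclass(frozen=True)
class Puff:
    """One smoke inhalation: time, inhalation length, Tx–Rx distance."""

    t_s: float
    duration_s: float
    tx_rx_distance_cm: float


@dataclass(frozen=True)
class Cigarette:
    t_light_s: float
    t_end_s: float
    puffs: tuple[Puff, ...]
    # activity during the session: "sit", "walk" or "stand"
    posture: str = "sit"


@dataclass(frozen=True)
class Breath:
    peak_time_s: float
    depth_fraction: float  # 0–1, 1 = deepest (smoke inhalations)


@dataclass
class BehaviorTimeline:
    """Latent ground truth for one simulated recording.

    ``hr_knots_s`` / ``hr_bpm`` define a piecewise-linear heart-rate
    profile; ``steps`` holds one ``(window_start_s, count)`` pair per
    pedometer buffer window (13.63 s); ``route`` arrays give the true
    position at 1 Hz with ``indoor_intervals`` marking satellite loss.
    """

    duration_s: float
    breaths: list[Breath] = field(default_factory=list)
    cigarettes: list[Cigarette] = field(default_factory=list)
    spurious_lighter_presses: list[float] = field(default_factory=list)
    steps: list[tuple[float, int]] = field(default_factory=list)
    hr_knots_s: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    hr_bpm: np.ndarray = field(default_factory=lambda: np.array([80.0, 80.0]))
    route_t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    route_lat_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    route_lon_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    indoor_intervals: list[tuple[float, float]] = field(default_factory=list)
    activities: list[tuple[float, float, str]] = field(default_factory=list)
    removal_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [b.peak_time_s for b in self.breaths]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise IntegrityError("breath times must be strictly increasing")
        if np.any(np.asarray(self.hr_bpm) <= 0):
            raise IntegrityError("heart-rate profile must be positive everywhere")
        for cig in self.cigarettes:
            for p in cig.puffs:
                if not (cig.t_light_s <= p.t_s <= cig.t_end_s):
                    raise IntegrityError("puff outside its cigarette interval")
                if p.tx_rx_distance_cm > 15:
                    raise IntegrityError("puff Tx–Rx distance exceeds 15 cm")

    def hr_at(self, t_s) -> np.ndarray:
        """Instantaneous mean heart rate (bpm) at time(s) *t_s*."""
        return np.interp(np.asarray(t_s, dtype=float), self.hr_knots_s, self.hr_bpm)

    @property
    def n_puffs(self) -> int:
        return sum(len(c.puffs) for c in self.cigarettes)

    @property
    def total_steps(self) -> int:
        return int(sum(c for _, c in self.steps))

    def smoking_intervals(self) -> list[tuple[float, float]]:
        return [(c.t_light_s, c.t_end_s) for c in self.cigarettes]


PEDOMETER_WINDOW_S = 13.63  # processor buffer fill time


@dataclass
class SimConfig:
    """Scenario parameters for :func:`simulate_behavior`.

    All randomness flows from ``seed``; two runs with the same config are
    identical.  Rates are per day regardless of ``duration_s``.
    """

    seed: int = 0
    duration_s: float = 86400.0
    controlled_duration_s: float = 10800.0  # supervised lab portion at the start
    cigarettes_per_day: float = 11.0
    puffs_per_cigarette: tuple[int, int] = (8, 12)  # inclusive uniform range
    puff_duration_s: tuple[float, float] = (1.5, 3.0)
    puff_distance_cm: tuple[float, float] = (5.0, 11.0)
    cigarette_duration_s: float = 300.0
    breathing_rate_bpm: tuple[float, float] = (12.0, 20.0)
    hr_baseline_bpm: float = 81.54
    hr_smoking_bpm: float = 112.03
    hr_recovery_s: float = 840.0  # back to baseline within 15 min of the session end
    hr_rise_s: float = 60.0
    walk_fraction: float = 0.12
    walk_cadence_spm: float = 105.0  # steps per minute while walking
    walk_speed_mps: float = 1.4
    spurious_press_rate_per_day: float = 0.5
    presses_per_lighting: tuple[int, int] = (1, 3)
    removal_intervals: tuple[tuple[float, float], ...] = ()
    start_lat_deg: float = 33.2098
    start_lon_deg: float = -87.5692
    drift_s_per_day: dict = field(
        default_factory=lambda: {"lighter": 5.0, "hand": 3.0, "chest": -4.0}
    )

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ConfigError("duration_s must be non-negative")
        if self.cigarettes_per_day < 0 or self.spurious_press_rate_per_day < 0:
            raise ConfigError("event rates must be non-negative")
        lo, hi = self.breathing_rate_bpm
        if not (0 < lo <= hi):
            raise ConfigError("breathing_rate_bpm range must be positive and ordered")


def _place_sessions(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[float, float]]:
    """Non-overlapping smoking sessions with pre/post margins for HR windows."""
    n = rng.poisson(cfg.cigarettes_per_day * cfg.duration_s / 86400.0)
    margin = 5 * 60.0 + cfg.hr_rise_s
    lo = margin
    hi = cfg.duration_s - cfg.cigarette_duration_s - cfg.hr_recovery_s - 60.0
    if hi <= lo or n == 0:
        return []
    gap = cfg.cigarette_duration_s + cfg.hr_recovery_s + 5 * 60.0
    sessions: list[tuple[float, float]] = []
    for _ in range(20 * n):
        if len(sessions) == n:
            break
        t0 = rng.uniform(lo, hi)
        t1 = t0 + cfg.cigarette_duration_s
        if all(t0 - gap > s1 or t1 + gap < s0 for s0, s1 in sessions):
            sessions.append((t0, t1))
    return sorted(sessions)


def _walk_segments(rng: np.random.Generator, cfg: SimConfig,
                   sessions: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Walking bouts (~8 min) covering roughly walk_fraction of the day,
    avoiding smoking sessions so sitting–smoking HR windows stay quiet."""
    segments: list[tuple[float, float]] = []
    target = cfg.walk_fraction * cfg.duration_s
    walked = 0.0
    guard = 20 * 60.0
    for _ in range(200):
        if walked >= target:
            break
        length = rng.uniform(5 * 60.0, 10 * 60.0)
        if cfg.duration_s <= length:
            break
        t0 = rng.uniform(0.0, cfg.duration_s - length)
        t1 = t0 + length
        if any(t0 < s1 + guard and t1 > s0 - guard for s0, s1 in sessions):
            continue
        if any(t0 < w1 + 60 and t1 > w0 - 60 for w0, w1 in segments):
            continue
        segments.append((t0, t1))
        walked += length
    return sorted(segments)


def simulate_behavior(config: SimConfig) -> BehaviorTimeline:
    """Draw one behavior timeline from the scenario *config*.

    The breath process is an inhomogeneous renewal process whose rate
    wanders inside ``breathing_rate_bpm``; each puff replaces the breath
    that would fall inside it with a deep smoke inhalation at the puff
    time.  Heart rate ramps from baseline to the smoking level within
    ``hr_rise_s`` of lighting, holds for the session, and relaxes back to
    baseline ``hr_recovery_s`` after the session ends.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.duration_s == 0:
        return BehaviorTimeline(duration_s=0.0)

    sessions = _place_sessions(rng, cfg)

    # --- cigarettes and puffs -------------------------------------------
    cigarettes = []
    for (t0, t1) in sessions:
        n_puffs = int(rng.integers(cfg.puffs_per_cigarette[0], cfg.puffs_per_cigarette[1] + 1))
        usable = (t1 - 10.0) - (t0 + 15.0)
        slots = t0 + 15.0 + usable * (np.arange(n_puffs) + 0.5) / n_puffs
        slots = slots + rng.uniform(-0.3, 0.3, n_puffs) * usable / n_puffs
        puffs = tuple(
            Puff(
                t_s=float(t),
                duration_s=float(rng.uniform(*cfg.puff_duration_s)),
                tx_rx_distance_cm=float(rng.uniform(*cfg.puff_distance_cm)),
            )
            for t in np.sort(slots)
        )
        cigarettes.append(Cigarette(t_light_s=t0, t_end_s=t1, puffs=puffs))

    # --- breath renewal process -----------------------------------------
    puff_list = sorted((p for c in cigarettes for p in c.puffs), key=lambda p: p.t_s)
    breaths: list[Breath] = []
    lo, hi = cfg.breathing_rate_bpm
    rate = rng.uniform(lo, hi)
    # keep every breath bump (half-width up to 2 s) fully inside the
    # recording so edge truncation cannot hide a peak from the detectors
    edge_s = 2.0
    t = edge_s + rng.uniform(0.0, 60.0 / rate)
    puff_idx = 0
    while t < cfg.duration_s - edge_s:
        # deep smoke inhalation overrides the tidal breath nearest the puff
        while puff_idx < len(puff_list) and puff_list[puff_idx].t_s < t - 1.0:
            puff_idx += 1
        if puff_idx < len(puff_list) and abs(puff_list[puff_idx].t_s - t) <= 60.0 / rate:
            t = puff_list[puff_idx].t_s
            breaths.append(Breath(peak_time_s=float(t), depth_fraction=1.0))
            puff_idx += 1
        else:
            breaths.append(Breath(peak_time_s=float(t), depth_fraction=float(rng.uniform(0.4, 0.8))))
        rate = float(np.clip(rate + rng.normal(0.0, 0.3), lo, hi))
        t += 60.0 / rate * float(rng.uniform(0.95, 1.05))

    # --- heart-rate profile ---------------------------------------------
    knots = [0.0]
    bpm = [cfg.hr_baseline_bpm]
    for c in cigarettes:
        knots += [c.t_light_s, c.t_light_s + cfg.hr_rise_s, c.t_end_s,
                  c.t_end_s + 0.3 * cfg.hr_recovery_s, c.t_end_s + cfg.hr_recovery_s]
        mid = cfg.hr_baseline_bpm + 0.35 * (cfg.hr_smoking_bpm - cfg.hr_baseline_bpm)
        bpm += [cfg.hr_baseline_bpm, cfg.hr_smoking_bpm, cfg.hr_smoking_bpm,
                mid, cfg.hr_baseline_bpm]
    knots.append(cfg.duration_s)
    bpm.append(cfg.hr_baseline_bpm)

    # --- walking, steps, route ------------------------------------------
    walks = _walk_segments(rng, cfg, sessions)
    steps: list[tuple[float, int]] = []
    w0 = 0.0
    while w0 < cfg.duration_s:
        w1 = min(w0 + PEDOMETER_WINDOW_S, cfg.duration_s)
        overlap = sum(max(0.0, min(w1, b) - max(w0, a)) for a, b in walks)
        count = int(round(overlap * cfg.walk_cadence_spm / 60.0))
        steps.append((w0, count))
        w0 += PEDOMETER_WINDOW_S

    route_t = np.arange(0.0, cfg.duration_s, 1.0)
    lat = np.full_like(route_t, cfg.start_lat_deg)
    lon = np.full_like(route_t, cfg.start_lon_deg)
    m_per_deg_lat = 111_195.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(cfg.start_lat_deg))
    cur_lat, cur_lon = cfg.start_lat_deg, cfg.start_lon_deg
    for (a, b) in walks:
        bearing = rng.uniform(0, 2 * np.pi)
        i0, i1 = np.searchsorted(route_t, [a, b])
        seg_t = route_t[i0:i1]
        if len(seg_t):
            dist = (seg_t - seg_t[0]) * cfg.walk_speed_mps
            lat[i0:i1] = cur_lat + dist * np.cos(bearing) / m_per_deg_lat
            lon[i0:i1] = cur_lon + dist * np.sin(bearing) / m_per_deg_lon
            cur_lat = float(lat[i1 - 1])
            cur_lon = float(lon[i1 - 1])
        lat[i1:] = cur_lat
        lon[i1:] = cur_lon

    # --- activity labels and indoor intervals ---------------------------
    marks = sorted(
        [(a, b, "walk") for a, b in walks]
        + [(c.t_light_s, c.t_end_s, "smoke_sit") for c in cigarettes]
    )
    activities: list[tuple[float, float, str]] = []
    cursor = 0.0
    for a, b, lab in marks:
        if a > cursor:
            activities.append((cursor, a, "sit"))
        activities.append((a, b, lab))
        cursor = b
    if cursor < cfg.duration_s:
        activities.append((cursor, cfg.duration_s, "sit"))
    indoor = [(a, b) for a, b, lab in activities if lab == "sit"]

    # --- spurious lighter presses outside sessions ----------------------
    n_spur = rng.poisson(cfg.spurious_press_rate_per_day * cfg.duration_s / 86400.0)
    spurious: list[float] = []
    for _ in range(50 * max(n_spur, 1)):
        if len(spurious) == n_spur:
            break
        t_sp = float(rng.uniform(0.0, cfg.duration_s))
        if all(not (s0 - 120.0 <= t_sp <= s1) for s0, s1 in sessions):
            spurious.append(t_sp)

    return BehaviorTimeline(
        duration_s=cfg.duration_s,
        breaths=breaths,
        cigarettes=cigarettes,
        spurious_lighter_presses=sorted(spurious),
        steps=steps,
        hr_knots_s=np.asarray(knots),
        hr_bpm=np.asarray(bpm),
        route_t_s=route_t,
        route_lat_deg=lat,
        route_lon_deg=lon,
        indoor_intervals=indoor,
        activities=activities,
        removal_intervals=list(cfg.removal_intervals),
    )
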