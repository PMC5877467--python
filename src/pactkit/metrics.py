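"""Bench-test computations and study-level summaries.

Covers the quantitative glue of the pipeline: LC-oscillator physics for
the respiratory inductance belt (resonant frequency, inductance
inversion, pulse-count-to-MHz conversion), linearity and agreement
statistics (R-squared, lagged cross-correlation), great-circle GPS
displacement, and the study summary report of per-portion event counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import IntegrityError, ParameterError, UndefinedStatisticError
from .logio import EventLog, UsabilityMask

__all__ = [
    "resonant_frequency_hz",
    "estimate_inductance",
    "count_to_mhz",
    "truncate",
    "linearity_r2",
    "xcorr_coefficient",
    "haversine_m",
    "displacement_stats",
    "SummaryReport",
    "summarize",
    "breath_variation_percent",
    "SUMMARY_ROWS",
]

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# LC-oscillator physics

def resonant_frequency_hz(l_henries: float, c_farads: float) -> float:
    """Resonant frequency of an LC tank: ``f0 = 1 / (2 pi sqrt(L C))``."""
    if l_henries <= 0 or c_farads <= 0:
        raise ParameterError("inductance and capacitance must be positive")
    return 1.0 / (2.0 * math.pi * math.sqrt(l_henries * c_farads))


def estimate_inductance(f0_hz: float, c_farads: float) -> float:
    """Invert the resonance formula: ``L = 1 / ((2 pi f0)^2 C)``."""
    if f0_hz <= 0 or c_farads <= 0:
        raise ParameterError("frequency and capacitance must be positive")
    return 1.0 / ((2.0 * math.pi * f0_hz) ** 2 * c_farads)


def truncate(value: float, ndigits: int = 2) -> float:
    """Truncate (not round) toward zero at *ndigits* decimals.

    Printed bench tables report frequencies truncated at two decimals;
    a tiny epsilon guards against binary representation of exact values
    (``10.00`` must not truncate to ``9.99``).
    """
    scale = 10 ** ndigits
    return math.trunc(round(value * scale, 6)) / scale


def count_to_mhz(mean_pulse_count_per_window: float, window_s: float = 0.01) -> float:
    """Convert a mean pulse count per counting window to MHz, truncated to
    two decimals as printed in the bench tables."""
    if mean_pulse_count_per_window <= 0 or window_s <= 0:
        raise ParameterError("count and window must be positive")
    return truncate(mean_pulse_count_per_window / window_s / 1e6, 2)


# ---------------------------------------------------------------------------
# agreement statistics

def linearity_r2(x, y) -> float:
    """Coefficient of determination of the ordinary least-squares line.

    Degenerate *x* (all equal) raises; a flat *y* (zero total sum of
    squares) returns 0.0, since the fitted line explains no variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ParameterError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("x values are all equal; slope undefined")
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def xcorr_coefficient(a, b, lags: str = "all", max_lag_frac: float = 0.5) -> float:
    """Normalized cross-correlation coefficient of two series.

    Both series are mean-removed.  With ``lags="all"`` (default) the
    maximum over integer lags of the cross-correlation, each lag
    normalized by the norms of the overlapping segments, is returned, so
    a pure sinusoid against a shifted copy of itself scores 1.0.  Lags
    are restricted to ``max_lag_frac`` of the shorter series (tiny
    overlaps make the normalized coefficient degenerate).  With
    ``lags="zero"`` the zero-lag (Pearson) coefficient is returned.  The
    value lies in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("series too short for a correlation")
    a0 = a - a.mean()
    b0 = b - b.mean()
    ea = float(np.sum(a0**2))
    eb = float(np.sum(b0**2))
    if ea == 0.0 or eb == 0.0:
        raise UndefinedStatisticError("zero-variance input")
    if lags == "zero":
        n = min(a0.size, b0.size)
        return float(
            np.dot(a0[:n], b0[:n])
            / math.sqrt(float(np.sum(a0[:n] ** 2)) * float(np.sum(b0[:n] ** 2)))
        )
    na, nb = a0.size, b0.size
    raw = _signal.correlate(a0, b0, mode="full", method="auto")
    # per-lag energies of the overlapping segments via cumulative sums
    ca = np.concatenate([[0.0], np.cumsum(a0**2)])
    cb = np.concatenate([[0.0], np.cumsum(b0**2)])
    best = -np.inf
    max_lag = int(max_lag_frac * min(na, nb))
    for lag in range(-max_lag, max_lag + 1):
        # overlap of a0[i] with b0[i - lag]
        ia0, ia1 = max(0, lag), min(na, nb + lag)
        if ia1 - ia0 < 2:
            continue
        ib0, ib1 = ia0 - lag, ia1 - lag
        e1 = ca[ia1] - ca[ia0]
        e2 = cb[ib1] - cb[ib0]
        if e1 == 0.0 or e2 == 0.0:
            continue
        v = raw[nb - 1 + lag] / math.sqrt(e1 * e2)
        best = max(best, float(v))
    if not np.isfinite(best):
        raise UndefinedStatisticError("no lag with a defined coefficient")
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# geodesy

def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ParameterError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if abs(lon) > 180:
            raise ParameterError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(h))


def _pairwise_haversine_m(lat, lon, ref_lat, ref_lon) -> np.ndarray:
    """Vectorized distance from each fix to every reference point (matrix)."""
    p = np.radians(np.asarray(lat, dtype=float))[:, None]
    q = np.radians(np.asarray(ref_lat, dtype=float))[None, :]
    dl = np.radians(np.asarray(lon, dtype=float))[:, None] - np.radians(
        np.asarray(ref_lon, dtype=float)
    )[None, :]
    h = np.sin((q - p) / 2) ** 2 + np.cos(p) * np.cos(q) * np.sin(dl / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def displacement_stats(track_lat, track_lon, ref_lat, ref_lon,
                       chunk: int = 2000) -> tuple[float, float]:
    """Mean and standard deviation (m) of each fix's distance to the
    nearest point of a reference route."""
    track_lat = np.asarray(track_lat, dtype=float)
    track_lon = np.asarray(track_lon, dtype=float)
    if track_lat.size == 0:
        raise ParameterError("empty track")
    mins = []
    for i in range(0, track_lat.size, chunk):
        d = _pairwise_haversine_m(
            track_lat[i : i + chunk], track_lon[i : i + chunk], ref_lat, ref_lon
        )
        mins.append(d.min(axis=1))
    dmin = np.concatenate(mins)
    return float(dmin.mean()), float(dmin.std(ddof=0))


# ---------------------------------------------------------------------------
# study summary

SUMMARY_ROWS = (
    "lighter_press_release",
    "cigarettes_from_lighter",
    "cigarettes_self_report",
    "h2m_from_imu",
    "breaths_rip",
    "breaths_bioimpedance",
    "h2m_proximity",
)

PORTIONS = ("controlled", "free_living")


def breath_variation_percent(breaths_rip: float, breaths_bioimpedance: float) -> float:
    """Relative disagreement of the two respiration sensors, in percent of
    the inductance-belt count (the reference sensor)."""
    if breaths_rip <= 0:
        raise UndefinedStatisticError("reference breath count must be positive")
    return (breaths_rip - breaths_bioimpedance) / breaths_rip * 100.0


@dataclass
class SummaryReport:
    """Per-portion behavioral/physiological event counts plus derived
    comparisons; ``total`` is always the sum of the two portions."""

    controlled: dict[str, int]
    free_living: dict[str, int]
    usable_percent: float | None = None
    false_lighter_events: dict[str, int] = field(default_factory=dict)
    hr_summary: dict | None = None

    def __post_init__(self) -> None:
        for d in (self.controlled, self.free_living):
            missing = [k for k in SUMMARY_ROWS if k not in d]
            if missing:
                raise IntegrityError(f"missing summary rows: {missing}")

    @property
    def total(self) -> dict[str, int]:
        return {k: self.controlled[k] + self.free_living[k] for k in SUMMARY_ROWS}

    @property
    def breath_variation_percent(self) -> float:
        t = self.total
        return breath_variation_percent(t["breaths_rip"], t["breaths_bioimpedance"])

    def to_dict(self) -> dict:
        out = {
            "controlled": dict(self.controlled),
            "free_living": dict(self.free_living),
            "total": self.total,
            "breath_variation_percent": self.breath_variation_percent
            if self.total["breaths_rip"] > 0
            else None,
        }
        if self.usable_percent is not None:
            out["usable_percent"] = self.usable_percent
        if self.false_lighter_events:
            out["false_lighter_events"] = dict(self.false_lighter_events)
        if self.hr_summary is not None:
            out["hr_summary"] = self.hr_summary
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _count(value) -> int:
    if isinstance(value, EventLog):
        return len(value)
    return int(value)


def summarize(
    portions: dict[str, dict],
    mask: UsabilityMask | None = None,
    portion_intervals: dict[str, tuple[float, float]] | None = None,
    false_lighter_events: dict[str, int] | None = None,
    hr_summary: dict | None = None,
) -> SummaryReport:
    """Assemble the study summary from per-portion event logs (or counts).

    Parameters
    ----------
    portions : dict
        ``{"controlled": {...}, "free_living": {...}}`` where each inner
        dict maps every name in :data:`SUMMARY_ROWS` to an
        :class:`~pactkit.logio.EventLog` or an integer count.
    mask : UsabilityMask, optional
        Usability screening result; contributes ``usable_percent``.
    portion_intervals : dict, optional
        ``{portion: (t_start, t_end)}``; if given, portions must be
        disjoint or an :class:`IntegrityError` is raised.
    """
    if set(portions) != set(PORTIONS):
        raise IntegrityError(f"portions must be exactly {PORTIONS}")
    if portion_intervals is not None:
        (a0, a1) = portion_intervals["controlled"]
        (b0, b1) = portion_intervals["free_living"]
        if a1 > b0 and b1 > a0:
            raise IntegrityError("study portions overlap")
    counts = {
        portion: {row: _count(portions[portion][row]) for row in SUMMARY_ROWS}
        for portion in PORTIONS
    }
    return SummaryReport(
        controlled=counts["controlled"],
        free_living=counts["free_living"],
        usable_percent=mask.usable_percent if mask is not None else None,
        false_lighter_events=false_lighter_events or {},
        hr_summary=hr_summary,
    )
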