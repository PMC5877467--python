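"""Linear clock-drift compensation across independent device clocks.

Each device runs its own crystal; frequency offsets of a few parts per
million accumulate to several seconds of relative drift per day.  The
study computer is treated as the master clock: every device is set to the
computer time ``t0`` at the start of recording, and at data extraction the
device time ``t_device`` and computer time ``t_pc`` are read in the same
instant.  The dimensionless correction factor

    f = (t_device - t0) / (t_pc - t0)

captures the device clock running fast (f > 1) or slow (f < 1), and raw
device timestamps ``t`` are mapped back to the reference clock by the
linear compensation

    t_c = (t - t0) / f + t0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .logio import Event, EventLog, SensorStream

__all__ = ["ClockModel", "fit_clock", "compensate", "compensate_log", "compensate_stream"]


@dataclass(frozen=True)
class ClockModel:
    """Per-device linear clock model.

    Attributes
    ----------
    device_id : str
    t0_s : float
        Reference time at which the device clock was initialized.
    f : float
        Correction factor; device elapsed time divided by reference
        elapsed time.  Must be positive.
    """

    device_id: str
    t0_s: float
    f: float

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ModelError(f"clock factor must be positive, got {self.f}")


def fit_clock(device_id: str, t0_s: float, t_device_s: float, t_pc_s: float) -> ClockModel:
    """Fit the correction factor from one paired read-out at extraction.

    Raises
    ------
    ModelError
        If the reference interval is degenerate (``t_pc_s <= t0_s``) or the
        implied factor is non-positive.
    """
    if t_pc_s <= t0_s:
        raise ModelError(
            f"degenerate reference interval: t_pc={t_pc_s} must exceed t0={t0_s}"
        )
    f = (t_device_s - t0_s) / (t_pc_s - t0_s)
    return ClockModel(device_id, t0_s, f)


def compensate(timestamps, clock: ClockModel):
    """Map device-clock timestamps to the reference clock, elementwise.

    Strictly monotone in its input; the exact inverse of the drift
    injection used by the simulator.
    """
    t = np.asarray(timestamps, dtype=float)
    out = (t - clock.t0_s) / clock.f + clock.t0_s
    if np.isscalar(timestamps) or t.ndim == 0:
        return float(out)
    return out


def compensate_log(log: EventLog, clock: ClockModel) -> EventLog:
    """Event log with every start/end timestamp moved to the reference clock."""
    events = [
        Event(
            e.kind,
            compensate(e.t_start_s, clock),
            compensate(e.t_end_s, clock),
            dict(e.attrs),
        )
        for e in log.events
    ]
    return EventLog(log.device_id, events)


def compensate_stream(stream: SensorStream, clock: ClockModel) -> SensorStream:
    """Stream with corrected start time and sampling rate.

    Sample values are untouched.  Within-file rate error is wholly absorbed
    by ``f``: compensating the start time and scaling the rate by ``f``
    regenerates every per-sample timestamp as ``compensate`` would.
    """
    from dataclasses import replace

    return replace(
        stream,
        start_time_s=compensate(stream.start_time_s, clock),
        sampling_rate_hz=stream.sampling_rate_hz * clock.f,
    )
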