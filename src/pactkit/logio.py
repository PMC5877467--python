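"""On-disk log formats and in-memory containers for the sensor suite.

Every device log is stored as delimited UTF-8 text so fixtures stay
inspectable:

``*.stream.csv``
    Uniformly sampled multi-channel series.  A short header block
    (``#device``, ``#rate_hz``, ``#units``) is followed by a CSV table
    ``t,<ch1>,<ch2>,...`` whose time column is on the device-local clock.

``*.events.csv``
    Discrete timestamped intervals (lighter presses, self-reported
    cigarettes, detected events) as ``kind,t_start,t_end,attrs_json``
    preceded by a ``#device`` header line.

Times are decimal seconds since a per-study epoch and remain device-local
until clock compensation is applied.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "SensorStream",
    "Event",
    "EventLog",
    "UsabilityMask",
    "EVENT_KINDS",
    "read_stream",
    "write_stream",
    "read_event_log",
    "write_event_log",
]

EVENT_KINDS = frozenset(
    {
        "lighter_press",
        "self_report_cigarette",
        "detected_breath",
        "detected_proximity",
        "detected_rpeak",
        "cigarette_estimate",
        "pedometer_window",
        "puff_truth",
        "breath_truth",
        "removal_truth",
    }
)


@dataclass
class SensorStream:
    """Uniformly sampled multi-channel series on a device-local clock.

    Parameters
    ----------
    device_id : str
        Identifier of the recording device (``lighter``, ``hand``, ``chest``).
    channels : list of str
        Channel names, one per data column.
    units : list of str
        Physical unit per channel (``g``, ``dps``, ``mV``, ``count``,
        ``degrees``, ``steps``).
    sampling_rate_hz : float
        Positive sampling rate; sample *i* is at
        ``start_time_s + i / sampling_rate_hz``.
    start_time_s : float
        Device-clock time of the first sample, seconds.
    data : numpy.ndarray
        Array of shape ``(n_samples, n_channels)``.
    """

    device_id: str
    channels: list[str]
    units: list[str]
    sampling_rate_hz: float
    start_time_s: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise IntegrityError(
                f"data has {self.data.shape[1] if self.data.ndim == 2 else '?'} "
                f"columns for {len(self.channels)} channels"
            )
        if len(self.units) != len(self.channels):
            raise IntegrityError("one unit string required per channel")
        if not self.sampling_rate_hz > 0:
            raise IntegrityError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Implied sample timestamps (device clock), strictly increasing."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D series for channel *name*."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r} in {self.channels}") from None
        return self.data[:, idx]

    def with_data(self, data: np.ndarray) -> "SensorStream":
        """Copy of the stream with the sample matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class Event:
    """One timestamped interval; instantaneous events have zero duration."""

    kind: str
    t_start_s: float
    t_end_s: float
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise IntegrityError(f"unknown event kind {self.kind!r}")
        if self.t_end_s < self.t_start_s:
            raise IntegrityError(
                f"event ends ({self.t_end_s}) before it starts ({self.t_start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class EventLog:
    """Sorted list of discrete events on one device clock."""

    device_id: str
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.t_start_s, e.t_end_s))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> "EventLog":
        return EventLog(self.device_id, [e for e in self.events if e.kind == kind])

    def starts(self) -> np.ndarray:
        return np.array([e.t_start_s for e in self.events], dtype=float)


@dataclass
class UsabilityMask:
    """Partition of a recording into usable / removed / ambiguous segments.

    Segments are ``(t_start_s, t_end_s, label)`` triples that are sorted,
    non-overlapping and cover the recording without gaps.
    """

    segments: list[tuple[float, float, str]]

    LABELS = ("usable", "removed", "ambiguous")

    def __post_init__(self) -> None:
        if not self.segments:
            raise IntegrityError("mask must cover a non-empty recording")
        self.segments = sorted(self.segments)
        prev_end = None
        for t0, t1, label in self.segments:
            if label not in self.LABELS:
                raise IntegrityError(f"unknown usability label {label!r}")
            if t1 < t0:
                raise IntegrityError("segment ends before it starts")
            if prev_end is not None and not np.isclose(t0, prev_end):
                raise IntegrityError("segments must tile the recording contiguously")
            prev_end = t1

    @property
    def t_start_s(self) -> float:
        return self.segments[0][0]

    @property
    def t_end_s(self) -> float:
        return self.segments[-1][1]

    def duration_s(self, label: str | None = None) -> float:
        return sum(
            t1 - t0
            for t0, t1, lab in self.segments
            if label is None or lab == label
        )

    def percent(self, label: str) -> float:
        """Share of total duration carrying *label*, in percent."""
        total = self.duration_s()
        if total == 0:
            raise IntegrityError("mask has zero duration")
        return 100.0 * self.duration_s(label) / total

    @property
    def usable_percent(self) -> float:
        return self.percent("usable")

    def label_at(self, t_s: float) -> str:
        for t0, t1, lab in self.segments:
            if t0 <= t_s < t1 or (t_s == t1 == self.t_end_s):
                return lab
        raise KeyError(f"time {t_s} outside mask [{self.t_start_s}, {self.t_end_s}]")


# ---------------------------------------------------------------------------
# stream I/O


def write_stream(stream: SensorStream, path) -> str:
    """Write *stream* to *path* in the ``*.stream.csv`` format.

    The round trip through :func:`read_stream` is lossless: floats are
    written with ``repr`` precision.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#device,{stream.device_id}\n")
        fh.write(f"#rate_hz,{stream.sampling_rate_hz!r}\n")
        fh.write(f"#start_s,{stream.start_time_s!r}\n")
        fh.write("#units," + ",".join(stream.units) + "\n")
        frame = pd.DataFrame(stream.data, columns=stream.channels)
        frame.insert(0, "t", stream.times())
        frame.to_csv(fh, index=False)
    return str(path)


def _parse_header(fh) -> dict:
    header: dict[str, str] = {}
    for _ in range(4):
        line = fh.readline().rstrip("\n")
        if not line.startswith("#"):
            raise FormatError("missing #-header block before data table")
        key, _, value = line[1:].partition(",")
        header[key] = value
    for key in ("device", "rate_hz", "start_s", "units"):
        if key not in header:
            raise FormatError(f"header line #{key} missing")
    return header


def read_stream(path) -> SensorStream:
    """Read a ``*.stream.csv`` file written by :func:`write_stream`.

    Raises
    ------
    FormatError
        Missing header block or malformed rows (the offending row index is
        reported).
    IntegrityError
        Non-monotonic or duplicated timestamps.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = _parse_header(fh)
        try:
            table = pd.read_csv(fh, dtype=float, float_precision="round_trip")
        except ValueError as exc:
            raise FormatError(f"malformed data table in {path}: {exc}") from exc
    if table.isna().any().any():
        bad = int(np.where(table.isna().any(axis=1))[0][0])
        raise FormatError(f"malformed row {bad} in {path}")
    if "t" not in table.columns:
        raise FormatError("data table must start with a 't' column")
    t = table["t"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.where(np.diff(t) <= 0)[0][0]) + 1
        raise IntegrityError(f"time column not strictly increasing at row {bad}")
    channels = [c for c in table.columns if c != "t"]
    units = header["units"].split(",") if header["units"] else []
    if units == [""] and not channels:
        units = []
    return SensorStream(
        device_id=header["device"],
        channels=channels,
        units=units,
        sampling_rate_hz=float(header["rate_hz"]),
        start_time_s=float(header["start_s"]),
        data=table[channels].to_numpy() if channels else np.empty((len(t), 0)),
    )


# ---------------------------------------------------------------------------
# event-log I/O


def write_event_log(log: EventLog, path) -> str:
    """Write *log* to *path* as ``kind,t_start,t_end,attrs_json`` rows."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#device,{log.device_id}\n")
        writer = csv.writer(fh)
        writer.writerow(["kind", "t_start", "t_end", "attrs_json"])
        for ev in log.events:
            writer.writerow(
                [ev.kind, repr(ev.t_start_s), repr(ev.t_end_s), json.dumps(ev.attrs)]
            )
    return str(path)


def read_event_log(path) -> EventLog:
    """Read a ``*.events.csv`` file; events are sorted on load.

    An event whose end precedes its start raises :class:`IntegrityError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#device,"):
            raise FormatError("missing #device header line")
        device_id = first.split(",", 1)[1]
        reader = csv.reader(fh)
        head = next(reader, None)
        if head is None or head[:3] != ["kind", "t_start", "t_end"]:
            raise FormatError("missing kind,t_start,t_end,attrs_json header row")
        events = []
        for i, row in enumerate(reader):
            if not row:
                continue
            if len(row) != 4:
                raise FormatError(f"malformed row {i} in {path}")
            kind, t0, t1, attrs = row
            try:
                t0f, t1f = float(t0), float(t1)
                attrs_map = json.loads(attrs) if attrs else {}
            except (ValueError, json.JSONDecodeError) as exc:
                raise FormatError(f"malformed row {i} in {path}: {exc}") from exc
            events.append(Event(kind, t0f, t1f, attrs_map))
    return EventLog(device_id, events)


def stream_to_text(stream: SensorStream) -> str:
    """Serialize a stream to its on-disk text form (for tests and debugging)."""
    buf = io.StringIO()
    buf.write(f"#device,{stream.device_id}\n")
    buf.write(f"#rate_hz,{stream.sampling_rate_hz!r}\n")
    buf.write(f"#start_s,{stream.start_time_s!r}\n")
    buf.write("#units," + ",".join(stream.units) + "\n")
    frame = pd.DataFrame(stream.data, columns=stream.channels)
    frame.insert(0, "t", stream.times())
    frame.to_csv(buf, index=False)
    return buf.getvalue()
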