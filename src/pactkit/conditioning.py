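"""Per-sensor denoising chains.

All filters are applied zero-phase (forward-backward) so event timestamps
feed cross-sensor comparisons without phase bias, and every stage is
length-preserving.  IIR stages use second-order-sections realizations;
this matters for the thoracic-impedance chain, whose 0.001 Hz high-pass
on 1 kHz data is numerically fragile in transfer-function form (the
implementation asserts the sections are finite and the filtered output
contains no NaNs).

Chains by sensor kind
---------------------
rip           first-order 0.1 Hz high-pass + 10-point Gaussian smoother
bioimpedance  first-order 0.001 Hz high-pass + 100-point Gaussian smoother
ecg           first-order 1 Hz high-pass + 60 Hz notch
imu           second-order 2 Hz low-pass
proximity     50-point Gaussian smoother
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import convolve1d

from .errors import ParameterError
from .logio import SensorStream

__all__ = [
    "highpass",
    "lowpass",
    "notch",
    "smooth_gaussian",
    "condition",
    "SENSOR_CHAINS",
]


def _check_cutoff(stream: SensorStream, cutoff_hz: float) -> None:
    nyquist = stream.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist} Hz)"
        )


def _apply_sos(stream: SensorStream, sos: np.ndarray) -> SensorStream:
    if not np.all(np.isfinite(sos)):
        raise ParameterError("filter design produced non-finite sections")
    out = _signal.sosfiltfilt(sos, stream.data, axis=0)
    if not np.all(np.isfinite(out)):
        raise ParameterError("filtering produced non-finite output")
    return stream.with_data(out)


def highpass(stream: SensorStream, cutoff_hz: float, order: int = 1) -> SensorStream:
    """Zero-phase Butterworth high-pass; removes DC and slow drift."""
    _check_cutoff(stream, cutoff_hz)
    sos = _signal.butter(
        order, cutoff_hz, btype="highpass", fs=stream.sampling_rate_hz, output="sos"
    )
    return _apply_sos(stream, sos)


def lowpass(stream: SensorStream, cutoff_hz: float, order: int = 2) -> SensorStream:
    """Zero-phase Butterworth low-pass."""
    _check_cutoff(stream, cutoff_hz)
    sos = _signal.butter(
        order, cutoff_hz, btype="lowpass", fs=stream.sampling_rate_hz, output="sos"
    )
    return _apply_sos(stream, sos)


def notch(stream: SensorStream, freq_hz: float = 60.0, q: float = 30.0) -> SensorStream:
    """Zero-phase IIR notch for power-line interference (Q = 30 keeps the
    stop band narrow enough to preserve QRS energy)."""
    _check_cutoff(stream, freq_hz)
    b, a = _signal.iirnotch(freq_hz, q, fs=stream.sampling_rate_hz)
    sos = _signal.tf2sos(b, a)
    return _apply_sos(stream, sos)


def gaussian_kernel(n_points: int) -> np.ndarray:
    """Normalized Gaussian kernel on *n_points* taps with sigma = n/6, so
    the kernel is effectively supported on its taps."""
    if n_points < 1:
        raise ParameterError("kernel needs at least one point")
    if n_points == 1:
        return np.ones(1)
    x = np.arange(n_points) - (n_points - 1) / 2.0
    sigma = n_points / 6.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_gaussian(stream: SensorStream, n_points: int) -> SensorStream:
    """Average-Gaussian smoother: convolution with a normalized Gaussian
    kernel of *n_points* taps (identity for a single tap).  The kernel is
    symmetric, so smoothing is zero-phase by construction."""
    k = gaussian_kernel(n_points)
    if len(k) == 1:
        return stream.with_data(stream.data.copy())
    out = convolve1d(stream.data, k, axis=0, mode="nearest")
    return stream.with_data(out)


SENSOR_CHAINS = {
    "rip": (("highpass", {"cutoff_hz": 0.1, "order": 1}), ("smooth_gaussian", {"n_points": 10})),
    "bioimpedance": (
        ("highpass", {"cutoff_hz": 0.001, "order": 1}),
        ("smooth_gaussian", {"n_points": 100}),
    ),
    "ecg": (("highpass", {"cutoff_hz": 1.0, "order": 1}), ("notch", {"freq_hz": 60.0})),
    "imu": (("lowpass", {"cutoff_hz": 2.0, "order": 2}),),
    "proximity": (("smooth_gaussian", {"n_points": 50}),),
}

_STAGES = {
    "highpass": highpass,
    "lowpass": lowpass,
    "notch": notch,
    "smooth_gaussian": smooth_gaussian,
}


def condition(stream: SensorStream, sensor_kind: str) -> SensorStream:
    """Run the denoising chain for *sensor_kind* over the stream.

    Raises
    ------
    ParameterError
        Unknown sensor kind, or a stage parameter incompatible with the
        stream's sampling rate.
    """
    try:
        chain = SENSOR_CHAINS[sensor_kind]
    except KeyError:
        raise ParameterError(
            f"unknown sensor kind {sensor_kind!r}; expected one of {sorted(SENSOR_CHAINS)}"
        ) from None
    out = stream
    for stage, params in chain:
        out = _STAGES[stage](out, **params)
    return out
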