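"""Raw counts to acceleration-magnitude series.

The chain, in order: scale 8-bit counts to m/s² (64 counts = 9.82 m/s²),
high-pass each axis with a 5th-order Butterworth at 3 Hz to strip gravity and
posture, take the per-sample Euclidean norm, then smooth with a 96-sample
moving average subsampled every 48 samples — reducing 32 Hz input to
32/48 ≈ 0.67 Hz.

Filtering precedes the norm: reversing the order would fold the gravity
component into the magnitude. The filter runs as a causal single pass with
zero initial state by default; a zero-phase forward-backward pass is
available via ``zero_phase``. The first ``transient_exclude_s`` seconds are
flagged as filter warm-up and excluded from downstream activity selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError, RangeError, ShapeError, TooShortError
from .raw_io import COUNT_MAX, COUNT_MIN, RawRecording

#: The device's count scale: 64 counts equal one standard gravity of 9.82 m/s².
GRAVITY_MS2 = 9.82
COUNTS_PER_G = 64.0


@dataclass(frozen=True)
class PreprocessParams:
    filter_order: int = 5
    cutoff_hz: float = 3.0
    zero_phase: bool = False
    window: int = 96
    stride: int = 48
    transient_exclude_s: float = 2.0


@dataclass(frozen=True)
class MagnitudeSeries:
    """Filtered, decimated acceleration magnitude in m/s².

    ``start_time`` is the epoch time at the center of the first averaging
    window. ``n_transient`` counts leading samples whose window overlaps the
    filter warm-up; they stay in the series (time alignment) but are skipped
    when selecting the most active samples.
    """

    arm_label: str
    start_time: float
    rate_hz: float
    values: np.ndarray
    n_transient: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ShapeError(f"values must be 1-D, got shape {arr.shape}")
        if arr.size and arr.min() < 0:
            raise RangeError("magnitude values must be nonnegative")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    def slice(self, start: int, stop: int | None = None) -> "MagnitudeSeries":
        stop = len(self.values) if stop is None else stop
        return MagnitudeSeries(
            arm_label=self.arm_label,
            start_time=self.start_time + start / self.rate_hz,
            rate_hz=self.rate_hz,
            values=self.values[start:stop],
            n_transient=max(0, self.n_transient - start),
        )


def counts_to_ms2(count):
    """Convert signed 8-bit counts to acceleration in m/s².

    Linear and sign-preserving: ``count * 9.82 / 64``, so a count of 64 maps
    to exactly one gravity (9.82 m/s²).
    """
    arr = np.asarray(count)
    if arr.size and (arr.min() < COUNT_MIN or arr.max() > COUNT_MAX):
        raise RangeError(f"count outside [{COUNT_MIN}, {COUNT_MAX}]")
    out = arr * (GRAVITY_MS2 / COUNTS_PER_G)
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


def highpass_filter(
    axis_series: np.ndarray,
    sample_rate_hz: float,
    order: int = 5,
    cutoff_hz: float = 3.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """High-pass one axis with a Butterworth filter; output length == input.

    Causal single pass with zero initial state by default; ``zero_phase``
    switches to a forward-backward pass (zero group delay, squared magnitude
    response).
    """
    x = np.asarray(axis_series, dtype=float)
    if x.ndim != 1:
        raise ShapeError("axis series must be 1-D")
    if cutoff_hz >= sample_rate_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({sample_rate_hz / 2} Hz)"
        )
    if len(x) < 3 * order:
        raise TooShortError(f"need at least {3 * order} samples for an order-{order} filter")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes (signal vector magnitude)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ShapeError("axes must be 1-D arrays of equal length")
    return np.sqrt(x * x + y * y + z * z)


def smooth_decimate(
    mag: np.ndarray,
    sample_rate_hz: float,
    window: int = 96,
    stride: int = 48,
    start_time: float = 0.0,
    arm_label: str = "left",
    n_transient: int | None = None,
) -> MagnitudeSeries:
    """Moving-average smoothing with strided subsampling.

    Output sample ``k`` is the mean of ``mag[k*stride : k*stride + window]``
    (left-aligned, half-open); trailing samples that do not fill a window are
    dropped, so the output length is ``floor((n - window)/stride) + 1``. The
    output rate is ``sample_rate_hz / stride`` and the first output carries
    the timestamp of its window center.
    """
    mag = np.asarray(mag, dtype=float)
    n = len(mag)
    if n < window:
        raise TooShortError(f"series of length {n} shorter than window {window}")
    n_out = (n - window) // stride + 1
    cs = np.concatenate(([0.0], np.cumsum(mag)))
    starts = np.arange(n_out) * stride
    values = (cs[starts + window] - cs[starts]) / window
    if n_transient is None:
        n_transient = 0
    return MagnitudeSeries(
        arm_label=arm_label,
        start_time=start_time + (window / 2) / sample_rate_hz,
        rate_hz=sample_rate_hz / stride,
        values=np.maximum(values, 0.0),  # guard against -0.0 / rounding
        n_transient=n_transient,
    )


def preprocess_recording(
    rec: RawRecording, params: PreprocessParams | None = None
) -> MagnitudeSeries:
    """Full chain: scale -> per-axis high-pass -> norm -> smooth/decimate."""
    p = params or PreprocessParams()
    accel = counts_to_ms2(rec.samples)
    filtered = np.empty_like(accel, dtype=float)
    for axis in range(3):
        filtered[:, axis] = highpass_filter(
            accel[:, axis],
            rec.sample_rate_hz,
            order=p.filter_order,
            cutoff_hz=p.cutoff_hz,
            zero_phase=p.zero_phase,
        )
    mag = magnitude(filtered[:, 0], filtered[:, 1], filtered[:, 2])
    # Windows whose start falls inside the warm-up span are flagged transient.
    warmup_samples = p.transient_exclude_s * rec.sample_rate_hz
    n_transient = 0 if p.zero_phase else math.ceil(warmup_samples / p.stride)
    return smooth_decimate(
        mag,
        rec.sample_rate_hz,
        window=p.window,
        stride=p.stride,
        start_time=rec.start_time,
        arm_label=rec.arm_label,
        n_transient=n_transient,
    )
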