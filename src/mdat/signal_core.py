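"""Signal conditioning for single-sensor surface EMG.

The device reports muscle activity on a 10-bit scale (0–1023). The chain
implemented here mirrors the controller firmware: rectification, a 2 Hz
Butterworth high-pass to strip electrode DC offset and slow baseline drift,
a short moving-average window that turns the rectified signal into a smooth
contraction envelope, and quantization onto the integer device scale. The
nominal upper band edge of the analog front end sits at the sampling limit,
so digitally only the high-pass side is realized; the sampling itself bounds
the upper edge.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
from scipy import signal as sps

DEVICE_MAX = 1023
#: Interval 0..1024 used for zone minimums; 1024 is the open upper bound.
DEVICE_BOUND = 1024

#: Nominal controller->app packet rate and the tablet's frame-capped
#: processing rate.
PACKET_RATE_HZ = 60.0
FRAME_RATE_HZ = 30.0


def frame_interval_ms(frame_rate_hz: float = FRAME_RATE_HZ) -> float:
    """Processing interval implied by a frame-capped rate (33.3 ms at 30 Hz)."""
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    return 1000.0 / frame_rate_hz


@dataclass(frozen=True)
class RawSignal:
    """A raw EMG-like voltage trace at a fixed sampling rate."""

    samples: np.ndarray
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class FilterConfig:
    """High-pass corner, smoothing window and Butterworth order."""

    highpass_hz: float = 2.0
    smoothing_window_ms: float = 50.0
    filter_order: int = 2

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")
        if self.smoothing_window_ms <= 0:
            raise ValueError("smoothing_window_ms must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    def validate_rate(self, sample_rate_hz: float) -> None:
        if self.highpass_hz >= sample_rate_hz / 2:
            raise ValueError(
                f"highpass_hz={self.highpass_hz} must sit below the Nyquist "
                f"frequency {sample_rate_hz / 2}"
            )

    def smoothing_window_samples(self, sample_rate_hz: float) -> int:
        return max(1, int(round(self.smoothing_window_ms * sample_rate_hz / 1000.0)))

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        self.validate_rate(sample_rate_hz)
        return sps.butter(
            self.filter_order, self.highpass_hz, btype="highpass",
            fs=sample_rate_hz, output="sos",
        )


@dataclass(frozen=True)
class ProcessedStream:
    """Quantized envelope on the 0–1023 device scale at the frame cadence."""

    values: np.ndarray
    frame_interval_ms: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", values)
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if values.size and (values.min() < 0 or values.max() > DEVICE_MAX):
            raise ValueError(f"values must lie in [0, {DEVICE_MAX}]")

    def __len__(self) -> int:
        return int(self.values.size)


def rectify(sig: RawSignal) -> RawSignal:
    """Full-wave rectification: sample-wise absolute value."""
    return replace(sig, samples=np.abs(sig.samples))


def filter_and_smooth(sig: RawSignal, cfg: FilterConfig | None = None) -> RawSignal:
    """High-pass the trace and smooth it with a moving average.

    The high-pass removes DC and baseline drift; the moving average over
    ``smoothing_window_ms`` produces the envelope. Applied after
    :func:`rectify` the result tracks contraction intensity.

    Raises
    ------
    ValueError
        If the trace is shorter than the filter warm-up length
        (three times the Butterworth section count times the order, the
        usual padding requirement) or the smoothing window.
    """
    cfg = cfg or FilterConfig()
    sos = cfg.sos(sig.sample_rate_hz)
    window = cfg.smoothing_window_samples(sig.sample_rate_hz)
    warmup = max(3 * (cfg.filter_order + 1), window)
    if len(sig) < warmup:
        raise ValueError(
            f"signal of length {len(sig)} is shorter than the filter "
            f"warm-up length {warmup}"
        )
    filtered = sps.sosfilt(sos, sig.samples)
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(filtered, kernel, mode="same")
    return replace(sig, samples=smoothed)


def _round_half_away(x: float) -> int:
    """Round half away from zero (the device convention, not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def quantize(value: float, scale: float = 1.0) -> int:
    """Scale, round half away from zero, and clamp onto [0, 1023]."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    return min(DEVICE_MAX, max(0, _round_half_away(value * scale)))


def envelope(sig: RawSignal, cfg: FilterConfig | None = None) -> np.ndarray:
    """Pre-quantization envelope: rectify then filter-and-smooth.

    Positively homogeneous in the input amplitude, which the synthetic
    contraction generator relies on for exact peak placement.
    """
    return filter_and_smooth(rectify(sig), cfg).samples


def process(
    sig: RawSignal,
    cfg: FilterConfig | None = None,
    global_scale: float = 1.0,
    frame_interval_ms: float = 1.0,
) -> ProcessedStream:
    """Run the full conditioning chain onto the quantized device scale."""
    env = envelope(sig, cfg)
    values = np.clip(
        np.where(env >= 0, np.floor(env * global_scale + 0.5),
                 np.ceil(env * global_scale - 0.5)),
        0, DEVICE_MAX,
    ).astype(int)
    return ProcessedStream(values=values, frame_interval_ms=frame_interval_ms)


def iter_frames(samples: np.ndarray, packet_rate_hz: float = PACKET_RATE_HZ,
                frame_rate_hz: float = FRAME_RATE_HZ):
    """Yield packets regrouped at the frame cadence, dropping nothing.

    The controller delivers ~60 packets/s but the app consumes them at a
    30 Hz frame cap; buffered packets are processed in arrival order at each
    frame tick, so concatenating the frames restores the sample stream.
    """
    samples = np.asarray(samples)
    if packet_rate_hz <= 0 or frame_rate_hz <= 0:
        raise ValueError("rates must be positive")
    per_frame = max(1, int(round(packet_rate_hz / frame_rate_hz)))
    n_packets = max(1, int(round(packet_rate_hz)))
    packet_bounds = np.linspace(0, samples.size, n_packets + 1).astype(int)
    packets = [samples[a:b] for a, b in zip(packet_bounds[:-1], packet_bounds[1:])]
    for i in range(0, len(packets), per_frame):
        chunk = packets[i:i + per_frame]
        yield np.concatenate(chunk) if chunk else samples[:0]


# ---------------------------------------------------------------------------
# CSV round-trip for raw and processed traces

def write_raw_csv(sig: RawSignal, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_rate_hz={sig.sample_rate_hz}\n")
        fh.write("sample\n")
        for v in sig.samples:
            fh.write(f"{float(v)!r}\n")


def read_raw_csv(path: Union[str, Path]) -> RawSignal:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# sample_rate_hz="):
            raise ValueError("missing sample-rate metadata line")
        rate = float(meta.split("=", 1)[1])
        header = fh.readline().strip()
        if header != "sample":
            raise ValueError("expected 'sample' header")
        body = fh.read()
    samples = np.loadtxt(io.StringIO(body), ndmin=1) if body.strip() else np.array([])
    return RawSignal(samples=samples, sample_rate_hz=rate)


def write_processed_csv(stream: ProcessedStream, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# frame_interval_ms={stream.frame_interval_ms}\n")
        fh.write("value\n")
        for v in stream.values:
            fh.write(f"{int(v)}\n")


def read_processed_csv(path: Union[str, Path]) -> ProcessedStream:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# frame_interval_ms="):
            raise ValueError("missing frame-interval metadata line")
        interval = float(meta.split("=", 1)[1])
        header = fh.readline().strip()
        if header != "value":
            raise ValueError("expected 'value' header")
        body = fh.read()
    values = (np.loadtxt(io.StringIO(body), dtype=int, ndmin=1)
              if body.strip() else np.array([], dtype=int))
    return ProcessedStream(values=values, frame_interval_ms=interval)
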