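"""Contraction ("flex") segmentation on the quantized envelope.

A flex is a maximal run of samples strictly above the resting baseline; its
peak is the largest value seen in the run. The peak is only defined once the
signal dips strictly below the baseline again, so the detector is a two-state
machine: idle until a sample exceeds resting, active (tracking a running
maximum) until a sample falls below resting, at which point one FlexEvent is
emitted. A sample exactly equal to resting neither opens nor closes a flex.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .signal_core import DEVICE_MAX, ProcessedStream


@dataclass(frozen=True)
class FlexEvent:
    """One contraction: its peak value and the sample span it covered."""

    peak: int
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.peak <= DEVICE_MAX:
            raise ValueError("peak out of device range")
        if self.start_index < 0 or self.end_index < self.start_index:
            raise ValueError("invalid event span")


@dataclass
class DetectorState:
    """Mutable detector phase; ``current_max`` is set iff active."""

    phase: str = "idle"  # "idle" | "active"
    current_max: Optional[int] = None
    start_index: Optional[int] = None
    index: int = 0

    @property
    def active(self) -> bool:
        return self.phase == "active"


def step(
    state: DetectorState, sample: int, resting: int
) -> tuple[DetectorState, Optional[FlexEvent]]:
    """Advance the detector by one sample; emit at most one event.

    Opening requires ``sample > resting``; closing requires
    ``sample < resting``. Equality leaves the phase unchanged.
    """
    if not 0 <= sample <= DEVICE_MAX:
        raise ValueError("sample out of device range")
    if not 0 <= resting <= DEVICE_MAX:
        raise ValueError("resting out of device range")
    event: Optional[FlexEvent] = None
    i = state.index
    if state.phase == "idle":
        if sample > resting:
            state = DetectorState("active", int(sample), i, i + 1)
        else:
            state = DetectorState("idle", None, None, i + 1)
    else:
        if sample < resting:
            event = FlexEvent(
                peak=int(state.current_max),
                start_index=int(state.start_index),
                end_index=i - 1,
            )
            state = DetectorState("idle", None, None, i + 1)
        else:
            state = DetectorState(
                "active", max(int(state.current_max), int(sample)),
                state.start_index, i + 1,
            )
    return state, event


def flush(state: DetectorState) -> tuple[DetectorState, Optional[FlexEvent]]:
    """Force-emit a still-open contraction (interactive use only)."""
    if state.phase == "active":
        event = FlexEvent(
            peak=int(state.current_max),
            start_index=int(state.start_index),
            end_index=state.index - 1,
        )
        return DetectorState(index=state.index), event
    return state, None


def detect_flexes(
    stream: Union[ProcessedStream, Iterable[int], np.ndarray], resting: int
) -> list[FlexEvent]:
    """Batch-segment a stream into completed flexes, ordered by onset.

    A contraction still open at end-of-stream is not emitted: its peak is
    undefined until the signal has dipped below resting.
    """
    values = stream.values if isinstance(stream, ProcessedStream) else np.asarray(
        list(stream), dtype=int
    )
    state = DetectorState()
    events: list[FlexEvent] = []
    for sample in values:
        state, event = step(state, int(sample), resting)
        if event is not None:
            events.append(event)
    return events


def write_event_csv(
    events: Iterable[FlexEvent], path: Union[str, Path], resting: int,
    timestamps: Optional[Iterable[float]] = None,
) -> None:
    rows = list(events)
    ts = list(timestamps) if timestamps is not None else [None] * len(rows)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_index", "end_index", "peak", "resting", "timestamp"])
        for ev, t in zip(rows, ts):
            writer.writerow([ev.start_index, ev.end_index, ev.peak, resting,
                             "" if t is None else t])


def read_event_csv(path: Union[str, Path]) -> list[FlexEvent]:
    events = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            events.append(FlexEvent(
                peak=int(row["peak"]),
                start_index=int(row["start_index"]),
                end_index=int(row["end_index"]),
            ))
    return events
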