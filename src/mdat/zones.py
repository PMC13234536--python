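"""Discretization zones: map contraction peaks to gestures; calibration.

Each gesture zone is an interval [minimum_i, minimum_{i+1}) on the 0–1023
device axis, with the top zone open-ended at 1024. A flex peak selects the
zone containing it; peaks at or below the lowest minimum select nothing.
Calibration "zooms in" the reading: a global scale chosen so the user's
maximum voluntary contraction lands near the top of the axis.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .signal_core import DEVICE_BOUND, DEVICE_MAX, _round_half_away


@dataclass(frozen=True)
class ThresholdSet:
    """Resting baseline plus ordered zone minimums on the post-scale axis."""

    resting: int
    zone_minimums: tuple[int, ...]
    global_scale: float = 1.0
    top_bound: int = DEVICE_BOUND

    def __post_init__(self) -> None:
        mins = tuple(int(m) for m in self.zone_minimums)
        object.__setattr__(self, "zone_minimums", mins)
        if not 0 <= self.resting <= DEVICE_MAX:
            raise ValueError("resting out of device range")
        if not mins:
            raise ValueError("at least one zone is required")
        if any(b <= a for a, b in zip(mins, mins[1:])):
            raise ValueError("zone_minimums must be strictly increasing")
        if mins[0] <= self.resting:
            raise ValueError("zone minimums must lie above resting")
        if mins[-1] >= self.top_bound:
            raise ValueError(f"zone minimums must lie below {self.top_bound}")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")

    @property
    def n_zones(self) -> int:
        return len(self.zone_minimums)

    def zone_bounds(self, zone: int) -> tuple[int, int]:
        """Half-open [lower, upper) bounds of 1-based ``zone``."""
        if not 1 <= zone <= self.n_zones:
            raise ValueError(f"zone {zone} out of range 1..{self.n_zones}")
        lower = self.zone_minimums[zone - 1]
        upper = (self.zone_minimums[zone]
                 if zone < self.n_zones else self.top_bound)
        return lower, upper

    def zone_center(self, zone: int) -> float:
        lower, upper = self.zone_bounds(zone)
        return (lower + upper) / 2.0


@dataclass(frozen=True)
class CalibrationResult:
    """Global scale derived from an observed MVC peak."""

    global_scale: float
    mvc_peak: int
    target_fraction: float


def make_equal_zones(
    n_zones: int, resting: int, global_scale: float = 1.0
) -> ThresholdSet:
    """Equal segmentation of the axis above resting into ``n_zones`` zones.

    The first minimum is ``resting + 1`` so every detected flex
    (peak > resting) falls in some zone; consecutive minimums differ by
    ``round((1024 - first) / n_zones)`` and the top zone absorbs the
    integer-rounding remainder up to 1024.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if resting >= DEVICE_MAX:
        raise ValueError("resting must leave room above it")
    first = resting + 1
    width = _round_half_away((DEVICE_BOUND - first) / n_zones)
    mins = tuple(first + width * k for k in range(n_zones))
    return ThresholdSet(resting=resting, zone_minimums=mins,
                        global_scale=global_scale)


def assign_zone(peak: int, thresholds: ThresholdSet) -> Optional[int]:
    """1-based zone containing ``peak``, or None below the lowest minimum."""
    if not 0 <= peak <= DEVICE_MAX:
        raise ValueError("peak out of device range")
    idx = bisect_right(thresholds.zone_minimums, peak)
    return idx if idx >= 1 else None


def calibrate(mvc_peak: int, target_fraction: float = 1.0) -> CalibrationResult:
    """Scale so a repeat of the MVC quantizes to round(target_fraction·1023)."""
    if mvc_peak < 1:
        raise ValueError("mvc_peak must be >= 1 (no measurable contraction)")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must lie in (0, 1]")
    scale = target_fraction * DEVICE_MAX / mvc_peak
    return CalibrationResult(global_scale=scale, mvc_peak=int(mvc_peak),
                             target_fraction=target_fraction)
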