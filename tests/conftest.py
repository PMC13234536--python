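"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the flex
oracle splits streams by hand, the zone oracle scans intervals linearly, and
the rank-statistic oracles work from first-principles rank formulas.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdat.zones import ThresholdSet, make_equal_zones


@pytest.fixture
def study_thresholds() -> ThresholdSet:
    """Five equal zones above the study's default resting baseline of 20."""
    return make_equal_zones(5, 20)


def brute_force_flex_peaks(values, resting) -> list[int]:
    """Split at samples < resting; a run counts iff it contains a sample
    > resting AND is terminated by a sample < resting before end-of-stream.
    Its peak is the max over the strictly-above-resting samples."""
    peaks = []
    run: list[int] = []
    for v in values:
        if v < resting:
            above = [s for s in run if s > resting]
            if above:
                peaks.append(max(above))
            run = []
        else:
            run.append(v)
    return peaks  # an unterminated trailing run is dropped by design


def brute_force_zone(peak, thresholds: ThresholdSet):
    """Linear interval scan over [minimum_i, minimum_{i+1})."""
    mins = list(thresholds.zone_minimums) + [thresholds.top_bound]
    for i in range(len(mins) - 1):
        if mins[i] <= peak < mins[i + 1]:
            return i + 1
    return None


def average_ranks(values) -> np.ndarray:
    """Midranks computed by explicit counting (no scipy)."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(values.size)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_force_kruskal_h(groups) -> float:
    """Tie-corrected H from the rank-sum definition."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = average_ranks(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g)
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction if correction > 0 else float("nan")


def brute_force_u(a, b) -> float:
    """Pair-count U for the a-side: #(a > b) + 0.5 * #(a == b)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_force_spearman(x, y) -> float:
    """Pearson correlation of midranks, computed from raw sums."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
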