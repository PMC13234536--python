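"""Cohort-level summary statistics from the MDAT evaluation study.

These printed summaries (cohort sizes, per-trial score means and SDs, SUS
and NASA-TLX cohort means, grip-strength by gender) are the study's
published aggregate results. They serve two roles here: as inputs to the
in-table arithmetic the reporting pipeline reproduces (overall columns,
weighted overall SUS, cohort gaps), and as the anchor for the synthetic
survey generator's default cohort profiles. Raw participant-level data were
not released, so these aggregates are the only empirical anchor available.
"""

from __future__ import annotations

COHORT_N: dict[str, int] = {"A1": 9, "A2": 10, "A3": 9, "B1": 26}

#: Per-trial mean scores (out of 15), trials 1..3.
TRIAL_SCORE_MEANS: dict[str, tuple[float, float, float]] = {
    "A1": (15.0, 15.0, 15.0),
    "A2": (8.9, 8.9, 9.6),
    "A3": (5.6, 5.3, 5.5),
    "B1": (15.0, 7.5, 5.0),
}

#: Per-trial score SDs, trials 1..3.
TRIAL_SCORE_SDS: dict[str, tuple[float, float, float]] = {
    "A1": (0.0, 0.0, 0.0),
    "A2": (1.5, 1.3, 1.8),
    "A3": (1.9, 0.7, 1.5),
    "B1": (0.1, 1.8, 1.5),
}

#: Overall System Usability Scale mean (SD) per cohort.
SUS_MEANS: dict[str, float] = {"A1": 75.0, "A2": 75.0, "A3": 63.3, "B1": 76.2}
SUS_SDS: dict[str, float] = {"A1": 18.9, "A2": 16.8, "A3": 16.2, "B1": 11.7}

TLX_SUBSCALES: tuple[str, ...] = (
    "mental", "physical", "temporal", "performance", "effort", "frustration",
)

#: NASA-TLX subscale means per cohort (0-100 rescaled), ordered as
#: TLX_SUBSCALES. The performance subscale is inversely oriented.
TLX_MEANS: dict[str, tuple[float, ...]] = {
    "A1": (3.9, 31.1, 4.4, 84.4, 33.3, 6.1),
    "A2": (11.0, 24.0, 20.0, 59.0, 33.0, 15.0),
    "A3": (20.6, 38.9, 8.3, 30.6, 43.3, 18.3),
    "B1": (18.3, 27.1, 21.5, 44.2, 37.7, 16.3),
}

TLX_SDS: dict[str, tuple[float, ...]] = {
    "A1": (6.6, 22.0, 7.1, 14.7, 24.5, 19.7),
    "A2": (16.7, 17.7, 23.6, 22.1, 19.6, 14.8),
    "A3": (29.7, 22.5, 8.9, 21.2, 29.2, 30.1),
    "B1": (23.7, 22.5, 21.1, 21.2, 25.9, 19.2),
}

#: Dominant-hand grip strength (kg) by self-reported gender: (n, mean, sd).
GRIP_BY_GENDER: dict[str, tuple[int, float, float]] = {
    "men": (12, 44.0, 11.2),
    "women": (40, 27.3, 4.6),
    "other": (2, 21.3, 0.6),
}


def overall_from_trial_means(trial_means) -> float:
    """Unweighted average of a cohort's three trial means (the table's
    'Average score' column)."""
    means = list(trial_means)
    return sum(means) / len(means)


def weighted_mean(means: dict[str, float], ns: dict[str, int]) -> float:
    """Sample-size-weighted grand mean across cohorts."""
    total = sum(ns[c] for c in means)
    return sum(means[c] * ns[c] for c in means) / total
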