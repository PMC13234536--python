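"""Psychometric scoring: SUS, NASA-TLX (raw), Edinburgh handedness.

SUS: ten items on 1-5; odd items contribute x-1, even items 5-x, and the
contribution sum is multiplied by 2.5 for a 0-100 score. NASA-TLX (raw
variant, no pairwise weighting): six 1-21 items each rescaled to 0-100 via
(x-1)*5; the performance subscale is inversely oriented (higher = better
perceived performance). EHI laterality quotient: (R-L)/(R+L)*100, with
LQ > 40 classified as right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TLX_SUBSCALES: tuple[str, ...] = (
    "mental", "physical", "temporal", "performance", "effort", "frustration",
)

RIGHT_HANDED_LQ_CUTOFF = 40.0


@dataclass(frozen=True)
class SUSResponse:
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        object.__setattr__(self, "items", items)
        if len(items) != 10:
            raise ValueError("SUS requires exactly 10 items")
        if any(not 1 <= v <= 5 for v in items):
            raise ValueError("SUS items must lie in [1, 5]")


@dataclass(frozen=True)
class TLXResponse:
    """Six raw 1-21 items in the canonical subscale order."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        object.__setattr__(self, "items", items)
        if len(items) != 6:
            raise ValueError("NASA-TLX requires exactly 6 items")
        if any(not 1 <= v <= 21 for v in items):
            raise ValueError("TLX items must lie in [1, 21]")

    @classmethod
    def from_mapping(cls, values: Mapping[str, int]) -> "TLXResponse":
        return cls(tuple(int(values[name]) for name in TLX_SUBSCALES))


@dataclass(frozen=True)
class EHIResponse:
    R: int
    L: int

    def __post_init__(self) -> None:
        if self.R < 0 or self.L < 0:
            raise ValueError("tallies must be nonnegative")
        if self.R + self.L == 0:
            raise ValueError("EHI requires at least one tallied response")


def score_sus(resp: SUSResponse | Sequence[int]) -> float:
    """0-100 usability score: 2.5 * sum(odd: x-1; even: 5-x)."""
    if not isinstance(resp, SUSResponse):
        resp = SUSResponse(tuple(resp))
    total = 0
    for i, x in enumerate(resp.items, start=1):
        total += (x - 1) if i % 2 == 1 else (5 - x)
    return 2.5 * total


def score_tlx(resp: TLXResponse | Sequence[int]) -> dict[str, float]:
    """Six 0-100 subscale scores plus a composite.

    Subscale = (item - 1) * 5. The composite (labeled
    ``composite_inverted_performance``) is the unweighted mean of the six
    subscales with performance inverted as 100 - performance, so that
    higher composite = higher workload throughout.
    """
    if not isinstance(resp, TLXResponse):
        resp = TLXResponse(tuple(resp))
    scores = {name: (x - 1) * 5.0 for name, x in zip(TLX_SUBSCALES, resp.items)}
    oriented = [
        100.0 - v if name == "performance" else v for name, v in scores.items()
    ]
    scores["composite_inverted_performance"] = float(np.mean(oriented))
    return scores


def score_ehi(resp: EHIResponse | None = None, R: int | None = None,
              L: int | None = None) -> float:
    """Laterality quotient (R-L)/(R+L)*100 in [-100, 100]."""
    if resp is None:
        resp = EHIResponse(int(R), int(L))
    return (resp.R - resp.L) / (resp.R + resp.L) * 100.0


def classify_handedness(lq: float) -> str:
    return "right" if lq > RIGHT_HANDED_LQ_CUTOFF else "not_right"


def score_survey_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a raw survey table row-wise.

    Expects columns sus_1..sus_10, tlx_<subscale> for the six canonical
    subscales, and ehi_r / ehi_l tallies. Returns a copy with appended
    sus_score, tlx_<subscale> 0-100 scores, tlx_composite, ehi_lq and
    handedness_class columns.
    """
    sus_cols = [f"sus_{i}" for i in range(1, 11)]
    tlx_cols = [f"tlx_{name}" for name in TLX_SUBSCALES]
    missing = [c for c in sus_cols + tlx_cols + ["ehi_r", "ehi_l"]
               if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    out = df.copy()
    out["sus_score"] = [
        score_sus(tuple(row)) for row in df[sus_cols].to_numpy()
    ]
    tlx_scores = [score_tlx(tuple(row)) for row in df[tlx_cols].to_numpy()]
    for name in TLX_SUBSCALES:
        out[f"tlx_{name}_score"] = [s[name] for s in tlx_scores]
    out["tlx_composite"] = [
        s["composite_inverted_performance"] for s in tlx_scores
    ]
    out["ehi_lq"] = [
        score_ehi(EHIResponse(int(r), int(l)))
        for r, l in zip(df["ehi_r"], df["ehi_l"])
    ]
    out["handedness_class"] = [classify_handedness(v) for v in out["ehi_lq"]]
    return out
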