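"""Headless cue game: randomized cues, one attempt each, scored out of 15.

Each trial presents ``n_cues`` randomized zone cues. The player responds with
one contraction per cue (no time limit, one attempt); the attempt succeeds
iff the contraction's peak lands inside the cued zone. Static cohorts play
all three trials at a fixed zone count (A1: 1, A2: 3, A3: 5); the
progressive cohort B1 advances 1 -> 3 -> 5 zones across its three trials.
The schedule is repeated on the right arm and then the left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

import numpy as np

from .flex_detector import FlexEvent, detect_flexes
from .signal_core import FilterConfig, RawSignal, process
from .zones import ThresholdSet, assign_zone, make_equal_zones

#: Zone counts per trial for each cohort in the study design.
COHORT_SCHEDULES: dict[str, tuple[int, int, int]] = {
    "A1": (1, 1, 1),
    "A2": (3, 3, 3),
    "A3": (5, 5, 5),
    "B1": (1, 3, 5),
}

DEFAULT_N_CUES = 15
DEFAULT_RESTING = 20


class Player(Protocol):
    """Anything that can answer a cue with a raw contraction trace."""

    def contraction_signal(
        self, target_zone: int, thresholds: ThresholdSet, rng: np.random.Generator
    ) -> Optional[RawSignal]:
        """Return the raw trace for one attempt, or None for no response."""


@dataclass(frozen=True)
class TrialConfig:
    n_zones: int
    thresholds: ThresholdSet
    n_cues: int = DEFAULT_N_CUES
    seed: int = 0
    balanced_cues: bool = False
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.n_cues < 1:
            raise ValueError("n_cues must be >= 1")
        if self.thresholds.n_zones != self.n_zones:
            raise ValueError("thresholds must have exactly n_zones zones")


@dataclass(frozen=True)
class SessionPlan:
    """Three-trial schedule for one cohort, played on each arm in turn."""

    cohort: str
    zones_per_trial: tuple[int, int, int] = ()
    arms: tuple[str, ...] = ("right", "left")
    rest_between_trials_s: int = 60
    resting: int = DEFAULT_RESTING
    global_scale: float = 1.0
    n_cues: int = DEFAULT_N_CUES

    def __post_init__(self) -> None:
        if not self.zones_per_trial:
            if self.cohort not in COHORT_SCHEDULES:
                raise ValueError(f"unknown cohort {self.cohort!r}")
            object.__setattr__(
                self, "zones_per_trial", COHORT_SCHEDULES[self.cohort]
            )
        if len(self.zones_per_trial) != 3:
            raise ValueError("a session plan has exactly 3 trials")


@dataclass(frozen=True)
class CueOutcome:
    cued_zone: int
    peak: Optional[int]
    assigned_zone: Optional[int]
    success: bool


@dataclass(frozen=True)
class TrialResult:
    per_cue: tuple[CueOutcome, ...]
    score: int

    def __post_init__(self) -> None:
        if self.score != sum(c.success for c in self.per_cue):
            raise ValueError("score must equal the number of successes")


@dataclass(frozen=True)
class SessionTrial:
    arm: str
    trial: int  # 1-based
    n_zones: int
    result: TrialResult


def generate_cues(
    n_zones: int,
    n_cues: int = DEFAULT_N_CUES,
    seed: Union[int, np.random.Generator] = 0,
    balanced: bool = False,
) -> np.ndarray:
    """Randomized 1-based cue sequence, reproducible from ``seed``.

    Default mode draws cues i.i.d. uniform over zones; ``balanced`` gives
    each zone an equal count (remainder spread over randomly chosen zones)
    and shuffles the order.
    """
    if n_zones < 1 or n_cues < 1:
        raise ValueError("n_zones and n_cues must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not balanced:
        return rng.integers(1, n_zones + 1, size=n_cues)
    base, rem = divmod(n_cues, n_zones)
    cues = np.repeat(np.arange(1, n_zones + 1), base)
    if rem:
        extra = rng.choice(np.arange(1, n_zones + 1), size=rem, replace=False)
        cues = np.concatenate([cues, extra])
    rng.shuffle(cues)
    return cues


def score_attempt(
    cued_zone: int, event: FlexEvent, thresholds: ThresholdSet
) -> bool:
    """True iff the attempt's peak fell inside the cued zone."""
    if not 1 <= cued_zone <= thresholds.n_zones:
        raise ValueError("cued_zone invalid for thresholds")
    return assign_zone(event.peak, thresholds) == cued_zone


def run_trial(
    user: Player,
    cfg: TrialConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrialResult:
    """Play one trial: one contraction per cue through the full DSP chain.

    The raw trace the player produces for each cue is conditioned
    (rectified, filtered, smoothed, scaled, quantized), segmented by the
    flex detector, and the first completed flex is the attempt. A cue with
    no completed flex is a failure with an absent peak.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    cues = generate_cues(cfg.n_zones, cfg.n_cues, rng, balanced=cfg.balanced_cues)
    outcomes: list[CueOutcome] = []
    for cue in cues:
        raw = user.contraction_signal(int(cue), cfg.thresholds, rng)
        event: Optional[FlexEvent] = None
        if raw is not None:
            stream = process(
                raw, cfg.filter_cfg, global_scale=cfg.thresholds.global_scale
            )
            events = detect_flexes(stream, cfg.thresholds.resting)
            event = events[0] if events else None
        if event is None:
            outcomes.append(CueOutcome(int(cue), None, None, False))
        else:
            assigned = assign_zone(event.peak, cfg.thresholds)
            outcomes.append(CueOutcome(
                int(cue), event.peak, assigned, assigned == int(cue)
            ))
    score = sum(o.success for o in outcomes)
    return TrialResult(per_cue=tuple(outcomes), score=score)


def run_session(
    user: Player, plan: SessionPlan, seed: int = 0
) -> list[SessionTrial]:
    """Play the cohort schedule on each arm; all randomness from ``seed``."""
    root = np.random.SeedSequence(seed)
    trials: list[SessionTrial] = []
    for arm, arm_seq in zip(plan.arms, root.spawn(len(plan.arms))):
        for trial_idx, (n_zones, trial_seq) in enumerate(
            zip(plan.zones_per_trial, arm_seq.spawn(len(plan.zones_per_trial))),
            start=1,
        ):
            thresholds = make_equal_zones(
                n_zones, plan.resting, plan.global_scale
            )
            cfg = TrialConfig(
                n_zones=n_zones, thresholds=thresholds, n_cues=plan.n_cues
            )
            rng = np.random.default_rng(trial_seq)
            result = run_trial(user, cfg, rng)
            trials.append(SessionTrial(arm, trial_idx, n_zones, result))
    return trials


def write_cue_log(
    trials: Sequence[SessionTrial], path: Union[str, Path],
    participant_id: Optional[str] = None, cohort: Optional[str] = None,
) -> None:
    """JSON-lines log, one record per cue."""
    with open(path, "w") as fh:
        for st in trials:
            for i, cue in enumerate(st.result.per_cue, start=1):
                fh.write(json.dumps({
                    "participant_id": participant_id,
                    "cohort": cohort,
                    "arm": st.arm,
                    "trial": st.trial,
                    "n_zones": st.n_zones,
                    "cue_number": i,
                    "prompt": f"Hit threshold {cue.cued_zone}!",
                    "cued_zone": cue.cued_zone,
                    "peak": cue.peak,
                    "assigned_zone": cue.assigned_zone,
                    "success": cue.success,
                }) + "\n")
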