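"""Synthetic participants: EMG traces, trial behavior, survey responses.

Stands in for the human participants the study tested. The behavioral model
is deliberately minimal: a participant answering a cue produces one
contraction whose processed peak is Normal(zone center, aim_sd) clipped to
the device scale, embedded between stretches of resting baseline noise.
``aim_sd`` (in device counts on the 0–1023 axis) is the single knob
controlling accuracy; the closed-form per-zone hit probability
Phi((u-mu)/sigma) - Phi((l-mu)/sigma) makes the model analytically
checkable and invertible (aim_sd is recoverable from hit rates).

Contraction bursts are raised-cosine envelopes whose amplitude is solved so
the burst's processed, quantized peak equals the sampled target exactly; the
conditioning chain is positively homogeneous in amplitude, so a short secant
iteration suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from . import study
from .game_engine import COHORT_SCHEDULES, SessionPlan, run_session
from .signal_core import DEVICE_MAX, FilterConfig, RawSignal, envelope, quantize
from .zones import ThresholdSet


@dataclass(frozen=True)
class UserModel:
    """One simulated participant's signal and aiming characteristics.

    aim_sd
        SD (device counts) of the Gaussian error around the cued zone's
        center; 0 means a perfect aimer.
    resting_noise_sd / resting_mean
        Baseline sensor noise in raw units; defaults keep the processed
        baseline well below the study's resting threshold of 20 counts.
    burst_duration_ms
        Contraction burst length; 300 ms is a comfortable brief flex.
    peak_floor
        Optional lower truncation for sampled peaks. Setting it to
        ``resting + 1`` models a participant who always produces a
        detectable flex, whatever its magnitude (the single-zone ceiling
        condition).
    """

    aim_sd: float = 0.0
    resting_noise_sd: float = 2.0
    resting_mean: float = 10.0
    burst_duration_ms: float = 300.0
    sample_rate_hz: float = 1000.0
    seed: int = 0
    peak_floor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.aim_sd < 0 or self.resting_noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.burst_duration_ms <= 0:
            raise ValueError("burst_duration_ms must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample_peak(
        self, target_zone: int, thresholds: ThresholdSet,
        rng: Optional[np.random.Generator] = None,
    ) -> int:
        """Draw the processed peak this user would produce for a cue."""
        rng = rng if rng is not None else self.rng()
        center = thresholds.zone_center(target_zone)
        peak = center if self.aim_sd == 0 else rng.normal(center, self.aim_sd)
        lo = 0 if self.peak_floor is None else self.peak_floor
        return quantize(float(np.clip(peak, lo, DEVICE_MAX)))

    def contraction_signal(
        self, target_zone: int, thresholds: ThresholdSet,
        rng: Optional[np.random.Generator] = None,
    ) -> RawSignal:
        return synth_contraction(target_zone, thresholds, self, rng)


@dataclass(frozen=True)
class SurveyProfile:
    """Mean item-response levels for one cohort's synthetic surveys."""

    sus_item_means: tuple[float, ...]
    tlx_item_means: tuple[float, ...]
    response_sd: float = 1.0
    ehi_right_bias: float = 0.9  # P(any one EHI tally goes to the right hand)

    def __post_init__(self) -> None:
        if len(self.sus_item_means) != 10:
            raise ValueError("SUS has 10 items")
        if len(self.tlx_item_means) != 6:
            raise ValueError("NASA-TLX has 6 items")
        if any(not 1 <= m <= 5 for m in self.sus_item_means):
            raise ValueError("SUS item means must lie in [1, 5]")
        if any(not 1 <= m <= 21 for m in self.tlx_item_means):
            raise ValueError("TLX item means must lie in [1, 21]")
        if self.response_sd < 0:
            raise ValueError("response_sd must be nonnegative")


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-amplitude raised-cosine burst envelope of length n."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * (t + 1) / (n + 1)))


def synth_resting(
    duration_ms: float, user: UserModel,
    rng: Optional[np.random.Generator] = None,
) -> RawSignal:
    """Baseline noise only: Gaussian sensor noise around the resting mean."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = rng if rng is not None else user.rng()
    n = max(1, int(round(duration_ms * user.sample_rate_hz / 1000.0)))
    samples = user.resting_mean + rng.normal(0.0, user.resting_noise_sd, size=n)
    return RawSignal(samples=np.clip(samples, 0.0, None),
                     sample_rate_hz=user.sample_rate_hz)


def synth_contraction(
    target_zone: int,
    thresholds: ThresholdSet,
    user: UserModel,
    rng: Optional[np.random.Generator] = None,
    cfg: Optional[FilterConfig] = None,
    rest_ms: float = 200.0,
) -> RawSignal:
    """One cue response: rest, a burst aimed at the cued zone, rest.

    The processed, quantized peak of the returned trace equals
    ``user.sample_peak(...)`` exactly: the burst amplitude is solved by
    secant iteration against the conditioning chain, which is positively
    homogeneous in amplitude. A sampled peak at or below the resting
    threshold yields a pure resting trace (no detectable flex).
    """
    rng = rng if rng is not None else user.rng()
    cfg = cfg or FilterConfig()
    target = user.sample_peak(target_zone, thresholds, rng)

    fs = user.sample_rate_hz
    n_rest = max(1, int(round(rest_ms * fs / 1000.0)))
    n_burst = max(8, int(round(user.burst_duration_ms * fs / 1000.0)))
    n_total = 2 * n_rest + n_burst
    noise = user.resting_mean + rng.normal(0.0, user.resting_noise_sd, n_total)
    noise = np.clip(noise, 0.0, None)

    if target <= thresholds.resting:
        return RawSignal(samples=noise, sample_rate_hz=fs)

    burst = np.zeros(n_total)
    burst[n_rest:n_rest + n_burst] = _raised_cosine(n_burst)

    scale = thresholds.global_scale

    def peak_at(amplitude: float) -> float:
        raw = RawSignal(samples=noise + amplitude * burst, sample_rate_hz=fs)
        return float(envelope(raw, cfg).max()) * scale

    # Homogeneity gives an excellent starting point from the pure burst.
    unit = float(envelope(RawSignal(burst, fs), cfg).max()) * scale
    a0 = target / unit
    a1 = a0 * 1.02 + 1e-9
    f0, f1 = peak_at(a0) - target, peak_at(a1) - target
    for _ in range(8):
        if abs(f1) < 1e-9 or f1 == f0:
            break
        a0, a1 = a1, a1 - f1 * (a1 - a0) / (f1 - f0)
        a1 = max(a1, 0.0)
        f0, f1 = f1, peak_at(a1) - target
    return RawSignal(samples=noise + a1 * burst, sample_rate_hz=fs)


def zone_hit_probability(
    zone: int, thresholds: ThresholdSet, aim_sd: float
) -> float:
    """Closed-form P(peak lands in the cued zone) under the aiming model.

    Accounts for clipping at the device ceiling (mass above 1023 clips into
    the top zone) and for the resting gate (a peak at or below resting is
    never a detectable flex).
    """
    from scipy.stats import norm

    lower, upper = thresholds.zone_bounds(zone)
    mu = thresholds.zone_center(zone)
    if aim_sd == 0:
        return float(lower <= mu < upper and mu > thresholds.resting)
    lo = max(lower, thresholds.resting + 1) - 0.5
    p = norm.cdf(upper - 0.5, mu, aim_sd) - norm.cdf(lo, mu, aim_sd)
    if upper >= DEVICE_MAX + 1:  # ceiling clip lands inside the top zone
        p += norm.sf(upper - 0.5, mu, aim_sd)
    return float(p)


def estimate_aim_sd(
    hits_by_zone: Mapping[int, tuple[int, int]], thresholds: ThresholdSet,
    bracket: tuple[float, float] = (1.0, 2000.0),
) -> float:
    """Maximum-likelihood aim_sd from per-zone (hits, attempts) counts.

    Inverts the closed-form hit probability by maximizing the binomial
    log-likelihood over sigma with scalar bounded optimization.
    """
    from scipy.optimize import minimize_scalar

    def neg_loglik(sigma: float) -> float:
        ll = 0.0
        for zone, (hits, n) in hits_by_zone.items():
            p = min(max(zone_hit_probability(zone, thresholds, sigma), 1e-12),
                    1 - 1e-12)
            ll += hits * math.log(p) + (n - hits) * math.log1p(-p)
        return -ll

    res = minimize_scalar(neg_loglik, bounds=bracket, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)


def default_population(
    median_aim_sd: float = 200.0, sigma_log: float = 0.3
) -> Callable[[np.random.Generator], UserModel]:
    """Participant factory: per-participant aim_sd ~ LogNormal.

    The default median of 200 counts gives a mid-range accuracy level
    (roughly 60% per-cue accuracy at 3 zones), a realistic novice level for
    this control scheme.
    """

    def draw(rng: np.random.Generator) -> UserModel:
        aim_sd = float(rng.lognormal(math.log(median_aim_sd), sigma_log))
        return UserModel(aim_sd=aim_sd, seed=int(rng.integers(2**31)))

    return draw


def simulate_cohort(
    cohort: str,
    n_participants: int,
    user_population: Optional[Callable[[np.random.Generator], UserModel]] = None,
    seed: int = 0,
    resting: int = 20,
    n_cues: int = 15,
) -> pd.DataFrame:
    """Simulate a full cohort: one row per participant × arm × trial."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if cohort not in COHORT_SCHEDULES:
        raise ValueError(f"unknown cohort {cohort!r}")
    user_population = user_population or default_population()
    root = np.random.SeedSequence(seed)
    rows = []
    plan = SessionPlan(cohort=cohort, resting=resting, n_cues=n_cues)
    for pseq in root.spawn(n_participants):
        rng = np.random.default_rng(pseq)
        participant_id = f"{rng.integers(10**7, 10**8):08d}"
        user = user_population(rng)
        for st in run_session(user, plan, seed=int(rng.integers(2**31))):
            rows.append({
                "participant_id": participant_id,
                "cohort": cohort,
                "arm": st.arm,
                "trial": st.trial,
                "n_zones": st.n_zones,
                "score": st.result.score,
            })
    return pd.DataFrame(rows)


def default_survey_profiles(response_sd: float = 2.0) -> dict[str, SurveyProfile]:
    """Cohort survey profiles anchored to the study's reported means.

    SUS item means are chosen so the noiseless score matches the cohort's
    reported SUS mean (odd items above the midpoint, even items below by a
    common offset); TLX item means invert the 0-100 rescaling of the
    reported subscale means.
    """
    profiles = {}
    for cohort in study.COHORT_N:
        sus_mean = study.SUS_MEANS[cohort]
        # score = 2.5 * sum(contribs); symmetric offset d around midpoint 3
        # gives contribution 2 + d per item -> d = sus_mean/25 - 2.
        d = sus_mean / 25.0 - 2.0
        sus_items = tuple(
            min(5.0, max(1.0, 3.0 + d if i % 2 == 0 else 3.0 - d))
            for i in range(10)
        )
        tlx_items = tuple(
            min(21.0, max(1.0, m / 5.0 + 1.0)) for m in study.TLX_MEANS[cohort]
        )
        profiles[cohort] = SurveyProfile(
            sus_item_means=sus_items, tlx_item_means=tlx_items,
            response_sd=response_sd,
        )
    return profiles


def synth_surveys(
    profile_by_cohort: Optional[Mapping[str, SurveyProfile]] = None,
    n_by_cohort: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw integer survey responses, one row per participant.

    Columns: cohort, participant_id, sus_1..sus_10 (1-5),
    tlx_<subscale> (1-21), ehi_r, ehi_l (tallies over 10 items).
    """
    profile_by_cohort = profile_by_cohort or default_survey_profiles()
    n_by_cohort = n_by_cohort or study.COHORT_N
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, n in n_by_cohort.items():
        profile = profile_by_cohort[cohort]
        for _ in range(n):
            row: dict[str, object] = {
                "cohort": cohort,
                "participant_id": f"{rng.integers(10**7, 10**8):08d}",
            }
            for i, m in enumerate(profile.sus_item_means, start=1):
                v = m + rng.normal(0.0, profile.response_sd) * (4.0 / 20.0)
                row[f"sus_{i}"] = int(np.clip(round(v), 1, 5))
            for name, m in zip(study.TLX_SUBSCALES, profile.tlx_item_means):
                v = m + rng.normal(0.0, profile.response_sd)
                row[f"tlx_{name}"] = int(np.clip(round(v), 1, 21))
            r = int(rng.binomial(10, profile.ehi_right_bias))
            row["ehi_r"], row["ehi_l"] = r, 10 - r
            rows.append(row)
    return pd.DataFrame(rows)
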