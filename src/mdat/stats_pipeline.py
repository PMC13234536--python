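"""Cohort statistics: the contrasts and effect sizes the study reports.

Test statistics come from scipy.stats; the effect sizes layered on top
(paired and pooled Cohen d, the Hedges g small-sample correction, the
average-SD standardized difference d_av, rank-biserial r) are computed here
with their conventional definitions. All tests are two-sided at alpha=.05
and nothing is adjusted for multiple comparisons, deliberately mirroring
the study's analysis plan. SDs use the n-1 (sample) denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sst

from . import study
from .surveys import TLX_SUBSCALES

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical contrast: estimate, CI, test, and effect sizes."""

    mean_diff: float
    ci95: tuple[float, float]
    statistic: float
    p: float
    df: Optional[float] = None
    cohen_d: Optional[float] = None
    hedges_g: Optional[float] = None
    d_av: Optional[float] = None
    rank_biserial: Optional[float] = None
    shapiro_p: Optional[float] = None
    wilcoxon_w: Optional[float] = None
    wilcoxon_p: Optional[float] = None
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("CI bounds out of order")
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def hedges_correction(df: float, exact: bool = False) -> float:
    """Small-sample bias factor J(df) multiplying Cohen d.

    Approximate form 1 - 3/(4 df - 1); the exact gamma-ratio form
    J = Gamma(df/2) / (sqrt(df/2) Gamma((df-1)/2)) is available for
    cross-checking.
    """
    if df <= 1:
        raise ValueError("df must exceed 1")
    if not exact:
        return 1.0 - 3.0 / (4.0 * df - 1.0)
    return math.exp(
        math.lgamma(df / 2.0)
        - 0.5 * math.log(df / 2.0)
        - math.lgamma((df - 1.0) / 2.0)
    )


def paired_t_with_gate(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA,
    exact_hedges: bool = False,
) -> ComparisonResult:
    """Paired two-sided t test with a Shapiro-Wilk normality gate.

    Cohen d (paired) = mean(diff)/sd(diff); Hedges g applies the
    small-sample correction at df = n-1. When Shapiro-Wilk on the paired
    differences has p < alpha, a Wilcoxon signed-rank sensitivity result is
    attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("paired test requires n >= 3")
    diff = x - y
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    dof = n - 1
    if sd_d == 0.0:
        t_stat = 0.0 if mean_d == 0 else math.copysign(math.inf, mean_d)
        p = 1.0 if mean_d == 0 else 0.0
        return ComparisonResult(
            mean_diff=mean_d, ci95=(mean_d, mean_d), statistic=t_stat, p=p,
            df=dof, flagged=True,
            note="zero-variance differences: effect size undefined",
        )
    res = sst.ttest_rel(x, y)
    tcrit = sst.t.ppf(1 - alpha / 2, dof)
    se = sd_d / math.sqrt(n)
    d = mean_d / sd_d
    g = d * hedges_correction(dof, exact=exact_hedges)
    shapiro_p = float(sst.shapiro(diff).pvalue)
    w = wp = None
    if shapiro_p < alpha:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wres = sst.wilcoxon(x, y)
        w, wp = float(wres.statistic), float(wres.pvalue)
    return ComparisonResult(
        mean_diff=mean_d, ci95=(mean_d - tcrit * se, mean_d + tcrit * se),
        statistic=float(res.statistic), p=float(res.pvalue), df=float(dof),
        cohen_d=d, hedges_g=g, shapiro_p=shapiro_p,
        wilcoxon_w=w, wilcoxon_p=wp,
    )


def welch_t(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA,
    exact_hedges: bool = False,
) -> ComparisonResult:
    """Welch two-sided t test with pooled Cohen d, Hedges g and d_av.

    The t statistic and Welch-Satterthwaite df come from the unequal-
    variance test; the effect sizes use their conventional definitions:
    pooled d with the pooled SD at df = n_a + n_b - 2, Hedges g = d * J(df),
    and d_av = mean difference over the plain average of the two SDs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    mean_diff = float(a.mean() - b.mean())
    sa, sb = float(a.std(ddof=1)), float(b.std(ddof=1))
    na, nb = a.size, b.size
    if sa == 0.0 and sb == 0.0:
        flagged = True
        if mean_diff == 0.0:
            return ComparisonResult(
                mean_diff=0.0, ci95=(0.0, 0.0), statistic=0.0, p=1.0,
                df=float(na + nb - 2), flagged=True,
                note="zero variance in both groups: statistic undefined",
            )
    res = sst.ttest_ind(a, b, equal_var=False)
    dof = float(res.df)
    ci = res.confidence_interval(1 - alpha)
    pooled_sd = math.sqrt(
        ((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2)
    )
    df_pooled = na + nb - 2
    d = mean_diff / pooled_sd if pooled_sd > 0 else None
    g = d * hedges_correction(df_pooled, exact=exact_hedges) if d is not None else None
    avg_sd = (sa + sb) / 2.0
    d_av = mean_diff / avg_sd if avg_sd > 0 else None
    return ComparisonResult(
        mean_diff=mean_diff, ci95=(float(ci.low), float(ci.high)),
        statistic=float(res.statistic), p=float(res.pvalue), df=dof,
        cohen_d=d, hedges_g=g, d_av=d_av,
    )


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H is 0 by construction
        return 0.0, 1.0
    res = sst.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Constant input leaves the correlation undefined; NaN is returned with a
    warning rather than raising, so batch reports can proceed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = sst.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float, float]:
    """Mann-Whitney U with rank-biserial effect size r = 1 - 2U/(n_a n_b).

    U counts the a-side wins (pairs with a > b plus half the ties), so
    complete dominance of ``a`` gives U = n_a n_b and r = -1; the magnitude
    is what the report tables carry. The p value uses the exact null
    distribution for small tie-free samples (both n <= 8) and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("samples must be non-empty")
    if method == "auto":
        ties = np.intersect1d(a, b).size > 0 or (
            np.unique(a).size < a.size or np.unique(b).size < b.size
        )
        method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else (
            "asymptotic"
        )
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    r = 1.0 - 2.0 * u / (a.size * b.size)
    return u, float(res.pvalue), r


# ---------------------------------------------------------------------------
# Report construction


@dataclass
class ReportBundle:
    """Raw (unrounded) tables mirroring the study's reporting layout."""

    performance: Optional[pd.DataFrame] = None
    between_cohort: Optional[pd.DataFrame] = None
    sus: Optional[pd.DataFrame] = None
    tlx: Optional[pd.DataFrame] = None
    tlx_pairwise: dict[str, pd.DataFrame] = field(default_factory=dict)
    grip: Optional[pd.DataFrame] = None
    warnings: list[str] = field(default_factory=list)


def _per_participant_trial_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Average each participant's two arms into one score per trial."""
    return (
        scores.groupby(["cohort", "participant_id", "trial"], as_index=False)
        ["score"].mean()
    )


def performance_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Cohort x trial mean (SD) plus the per-participant overall column."""
    per = _per_participant_trial_scores(scores)
    rows = []
    for cohort, grp in per.groupby("cohort"):
        row: dict[str, object] = {"cohort": cohort}
        for trial in (1, 2, 3):
            vals = grp.loc[grp["trial"] == trial, "score"]
            row[f"trial{trial}_mean"] = vals.mean()
            row[f"trial{trial}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        overall = grp.groupby("participant_id")["score"].mean()
        row["overall_mean"] = overall.mean()
        row["overall_sd"] = overall.std(ddof=1) if len(overall) > 1 else 0.0
        row["n"] = grp["participant_id"].nunique()
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cohort").reset_index(drop=True)


def between_cohort_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Matched-trial Welch contrasts: B1 trial k vs static cohort k.

    B1's trial 1/2/3 is compared with A1 trial 1, A2 trial 2 and A3
    trial 3, matching both the zone count and the exposure time.
    """
    per = _per_participant_trial_scores(scores)
    rows = []
    for trial, static in ((1, "A1"), (2, "A2"), (3, "A3")):
        b1 = per.loc[(per["cohort"] == "B1") & (per["trial"] == trial), "score"]
        aa = per.loc[(per["cohort"] == static) & (per["trial"] == trial), "score"]
        if b1.empty or aa.empty:
            continue
        res = welch_t(b1.to_numpy(), aa.to_numpy())
        rows.append({
            "comparison": f"B1 vs {static}, trial {trial}",
            "mean_diff": res.mean_diff,
            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "welch_t": res.statistic, "df": res.df,
            "hedges_g": res.hedges_g, "d_av": res.d_av, "p": res.p,
        })
    return pd.DataFrame(rows)


def sus_table(surveys: pd.DataFrame) -> pd.DataFrame:
    """SUS mean (SD) per cohort plus the size-weighted overall row."""
    rows = []
    means, ns = {}, {}
    for cohort, grp in surveys.groupby("cohort"):
        vals = grp["sus_score"]
        rows.append({"cohort": cohort, "sus_mean": vals.mean(),
                     "sus_sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "n": len(vals)})
        means[cohort], ns[cohort] = float(vals.mean()), len(vals)
    rows.append({
        "cohort": "Overall",
        "sus_mean": study.weighted_mean(means, ns),
        "sus_sd": surveys["sus_score"].std(ddof=1),
        "n": len(surveys),
    })
    return pd.DataFrame(rows)


def tlx_table(surveys: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort TLX subscale means (SD) with a Kruskal-Wallis p row."""
    rows = []
    for cohort, grp in surveys.groupby("cohort"):
        row: dict[str, object] = {"cohort": cohort, "n": len(grp)}
        for name in TLX_SUBSCALES:
            vals = grp[f"tlx_{name}_score"]
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        row["overall_mean"] = grp["tlx_composite"].mean()
        row["overall_sd"] = (grp["tlx_composite"].std(ddof=1)
                             if len(grp) > 1 else 0.0)
        rows.append(row)
    out = pd.DataFrame(rows)
    cohorts = sorted(surveys["cohort"].unique())
    if len(cohorts) >= 2:
        prow: dict[str, object] = {"cohort": "KW p", "n": len(surveys)}
        for name in TLX_SUBSCALES:
            groups = [
                surveys.loc[surveys["cohort"] == c, f"tlx_{name}_score"]
                for c in cohorts
            ]
            try:
                _, p = kruskal_wallis(*groups)
            except ValueError:
                p = float("nan")
            prow[f"{name}_mean"] = p
        _, prow["overall_mean"] = kruskal_wallis(*[
            surveys.loc[surveys["cohort"] == c, "tlx_composite"]
            for c in cohorts
        ])
        out = pd.concat([out, pd.DataFrame([prow])], ignore_index=True)
    return out


def tlx_pairwise_table(surveys: pd.DataFrame, subscale: str) -> pd.DataFrame:
    """All pairwise Welch contrasts for one subscale, most significant first."""
    col = f"tlx_{subscale}_score"
    cohorts = sorted(surveys["cohort"].unique())
    rows = []
    for i, c1 in enumerate(cohorts):
        for c2 in cohorts[i + 1:]:
            a = surveys.loc[surveys["cohort"] == c1, col].to_numpy()
            b = surveys.loc[surveys["cohort"] == c2, col].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            res = welch_t(a, b)
            # SE of d_av via the Welch SE scaled by the same denominator
            se_dav = None
            avg_sd = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
            if avg_sd > 0:
                se_dav = math.sqrt(
                    a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
                ) / avg_sd
            rows.append({
                "comparison": f"{c1}, {c2}", "d_av": res.d_av,
                "d_av_se": se_dav, "p": res.p,
            })
    return (pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
            if rows else pd.DataFrame(rows))


def grip_table(grip: pd.DataFrame) -> pd.DataFrame:
    """Grip strength (kg) by self-reported gender, with a Mann-Whitney
    contrast for the two largest groups."""
    rows = []
    for gender, grp in grip.groupby("gender"):
        vals = grp["grip_kg"]
        rows.append({"gender": gender, "n": len(vals),
                     "grip_mean": vals.mean(),
                     "grip_sd": vals.std(ddof=1) if len(vals) > 1 else 0.0})
    out = pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(
        drop=True
    )
    if len(out) >= 2:
        g1, g2 = out.loc[0, "gender"], out.loc[1, "gender"]
        u, p, r = mann_whitney(
            grip.loc[grip["gender"] == g1, "grip_kg"].to_numpy(),
            grip.loc[grip["gender"] == g2, "grip_kg"].to_numpy(),
        )
        out.attrs["mann_whitney"] = {
            "groups": (str(g1), str(g2)), "U": u, "p": p, "rank_biserial": r,
        }
    return out


def build_report(
    scores: Optional[pd.DataFrame],
    surveys: Optional[pd.DataFrame] = None,
    grip: Optional[pd.DataFrame] = None,
    pairwise_subscales: Sequence[str] = ("performance", "temporal"),
) -> ReportBundle:
    """Assemble the full report bundle; degrade gracefully on missing parts."""
    bundle = ReportBundle()
    if scores is not None and not scores.empty:
        bundle.performance = performance_table(scores)
        bundle.between_cohort = between_cohort_table(scores)
        missing = set(study.COHORT_N) - set(scores["cohort"].unique())
        if missing:
            msg = f"missing cohorts in scores: {sorted(missing)}"
            bundle.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    if surveys is not None and not surveys.empty:
        if "sus_score" not in surveys.columns:
            raise ValueError("surveys table must be scored first")
        bundle.sus = sus_table(surveys)
        bundle.tlx = tlx_table(surveys)
        for name in pairwise_subscales:
            bundle.tlx_pairwise[name] = tlx_pairwise_table(surveys, name)
    else:
        bundle.warnings.append("survey sections absent")
    if grip is not None and not grip.empty:
        bundle.grip = grip_table(grip)
    return bundle


def write_report(bundle: ReportBundle, outdir: Union[str, Path]) -> None:
    """Write the bundle as CSV tables at the study's printed precision
    (means/SDs at 1 decimal, differences and CI bounds at 2)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def rounded(df: pd.DataFrame, two_dp: Sequence[str] = ()) -> pd.DataFrame:
        out = df.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].round(2 if col in two_dp else 1)
        return out

    if bundle.performance is not None:
        rounded(bundle.performance).to_csv(
            outdir / "performance_by_cohort.csv", index=False
        )
    if bundle.between_cohort is not None:
        rounded(
            bundle.between_cohort,
            two_dp=("mean_diff", "ci_low", "ci_high", "hedges_g", "d_av", "p"),
        ).to_csv(outdir / "between_cohort.csv", index=False)
    if bundle.sus is not None:
        rounded(bundle.sus).to_csv(outdir / "sus_by_cohort.csv", index=False)
    if bundle.tlx is not None:
        rounded(bundle.tlx).to_csv(outdir / "tlx_by_cohort.csv", index=False)
    for name, table in bundle.tlx_pairwise.items():
        rounded(table, two_dp=("d_av", "d_av_se", "p")).to_csv(
            outdir / f"tlx_pairwise_{name}.csv", index=False
        )
    if bundle.grip is not None:
        rounded(bundle.grip).to_csv(outdir / "grip_by_gender.csv", index=False)
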