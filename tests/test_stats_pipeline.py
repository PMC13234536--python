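"""Statistical contrasts: formula-level oracles and report assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_force_kruskal_h, brute_force_spearman, brute_force_u,
)
from mdat import study
from mdat.simulated_user import UserModel, simulate_cohort, synth_surveys
from mdat.stats_pipeline import (
    build_report, hedges_correction, kruskal_wallis, mann_whitney,
    paired_t_with_gate, spearman, welch_t, write_report,
)
from mdat.surveys import score_survey_table


class TestPairedT:
    def test_identical_pairs_degenerate(self):
        res = paired_t_with_gate([3, 3, 3, 3], [3, 3, 3, 3])
        assert res.statistic == 0.0 and res.p == 1.0
        assert res.flagged and res.cohen_d is None

    def test_matches_formula_level_computation(self):
        """Ten-pair fixture vs the textbook t = mean(d) / (sd(d)/sqrt(n))."""
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 10)
        y = x + rng.normal(0.5, 1, 10)
        res = paired_t_with_gate(x, y)
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(10))
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.df == 9
        assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)
        assert res.hedges_g == pytest.approx(res.cohen_d * (1 - 3 / 35), abs=1e-12)
        assert res.wilcoxon_w is None  # normal-looking differences

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(0.4, 1.2, size=12)
        res = paired_t_with_gate(x, y)
        ref = pingouin.ttest(x, y, paired=True)
        assert res.statistic == pytest.approx(float(ref["T"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_skewed_differences_trigger_wilcoxon_gate(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 1, 12)
        x = y + rng.lognormal(0, 1.2, 12)  # heavily skewed differences
        res = paired_t_with_gate(x, y)
        assert res.shapiro_p < 0.05
        assert res.wilcoxon_w is not None and res.wilcoxon_p is not None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_t_with_gate([1, 2], [3, 4])


class TestWelchT:
    def test_identical_groups_are_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(a, a)
        assert res.statistic == 0.0 and res.mean_diff == 0.0
        assert res.cohen_d == 0.0

    def test_d_av_formula(self):
        a = [1.0, 3.0, 5.0]   # mean 3, sd 2
        b = [-4.0, 0.0, 4.0]  # mean 0, sd 4
        res = welch_t(a, b)
        assert res.mean_diff == pytest.approx(3.0)
        assert res.d_av == pytest.approx(3.0 / 3.0)

    def test_sign_favors_larger_group_mean(self):
        rng = np.random.default_rng(0)
        b1 = rng.normal(7.5, 1.8, 26)
        a2 = rng.normal(8.9, 1.3, 10)
        res = welch_t(b1, a2)
        assert res.mean_diff < 0 and res.statistic < 0

    def test_matches_pingouin_welch(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(44)
        a = rng.normal(5, 2, 9)
        b = rng.normal(6.2, 3.5, 14)
        res = welch_t(a, b)
        ref = pingouin.ttest(a, b, correction=True)
        assert res.statistic == pytest.approx(float(ref["T"].iloc[0]), abs=1e-9)
        assert res.df == pytest.approx(float(ref["dof"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)
        ci_low, ci_high = ref["CI95"].iloc[0]
        assert res.ci95[0] == pytest.approx(ci_low, abs=0.01)
        assert res.ci95[1] == pytest.approx(ci_high, abs=0.01)

    def test_effect_size_identities(self):
        """g/d = J(df) and d_av = mean diff / average SD, on emitted results."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.normal(0, 1, rng.integers(4, 12))
            b = rng.normal(0.8, 2, rng.integers(4, 12))
            res = welch_t(a, b)
            df_pooled = len(a) + len(b) - 2
            assert res.hedges_g / res.cohen_d == pytest.approx(
                1 - 3 / (4 * df_pooled - 1), abs=1e-12
            )
            avg_sd = (np.std(a, ddof=1) + np.std(b, ddof=1)) / 2
            assert res.d_av == pytest.approx(res.mean_diff / avg_sd, abs=1e-12)

    def test_zero_variance_equal_means_flagged(self):
        res = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.flagged and res.p == 1.0


class TestHedgesCorrection:
    def test_approximation_close_to_exact_gamma_form(self):
        for df in (4, 9, 20, 50):
            approx = hedges_correction(df)
            exact = hedges_correction(df, exact=True)
            assert approx == pytest.approx(exact, abs=5e-3)


class TestRankStatistics:
    def test_kruskal_identical_groups_give_zero(self):
        h, p = kruskal_wallis([5.0] * 4, [5.0] * 5, [5.0] * 3)
        assert h == 0.0

    def test_kruskal_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            groups = [rng.integers(0, 8, rng.integers(2, 5)).astype(float)
                      for _ in range(rng.integers(2, 4))]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _ = kruskal_wallis(*groups)
            assert h == pytest.approx(brute_force_kruskal_h(groups), abs=1e-10)

    def test_separated_groups_match_hand_oracle(self):
        groups = [[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]]
        h, p = kruskal_wallis(*groups)
        assert h == pytest.approx(brute_force_kruskal_h(groups), abs=1e-10)
        assert p < 0.01

    def test_two_group_kruskal_equals_squared_standardized_u(self):
        rng = np.random.default_rng(30)
        a = rng.permutation(np.arange(20.0))[:8]   # tie-free
        b = np.arange(100.0, 112.0)
        h, _ = kruskal_wallis(a, b)
        u, _, _ = mann_whitney(a, b, method="asymptotic")
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [])

    def test_mann_whitney_matches_pair_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.integers(0, 10, rng.integers(1, 12)).astype(float)
            b = rng.integers(0, 10, rng.integers(1, 12)).astype(float)
            u, _, r = mann_whitney(a, b)
            u_oracle = brute_force_u(a, b)
            assert u == pytest.approx(u_oracle)
            assert r == pytest.approx(1 - 2 * u_oracle / (len(a) * len(b)))

    def test_mann_whitney_complete_dominance(self):
        u, _, r = mann_whitney([10, 11, 12], [1, 2, 3])
        assert u == 9 and r == -1.0

    def test_mann_whitney_symmetric_samples(self):
        u, _, r = mann_whitney([1, 3, 5, 7], [2, 4, 6, 0])
        assert abs(r) <= 0.5  # interleaved: near-zero effect

    def test_spearman_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_spearman_matches_midrank_oracle_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_spearman_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho)


@pytest.fixture(scope="module")
def score_table():
    pop = lambda rng: UserModel(
        aim_sd=float(rng.lognormal(math.log(150), 0.2)),
        peak_floor=21, seed=int(rng.integers(2**31)),
    )
    frames = [simulate_cohort(c, 4, pop, seed=i)
              for i, c in enumerate(("A1", "A2", "A3", "B1"))]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def scored_surveys():
    return score_survey_table(
        synth_surveys(n_by_cohort={c: 5 for c in study.COHORT_N}, seed=2)
    )


class TestReport:
    def test_ceiling_cohort_row(self, score_table):
        bundle = build_report(score_table)
        perf = bundle.performance.set_index("cohort")
        assert perf.loc["A1", "trial1_mean"] == 15.0
        assert perf.loc["A1", "overall_sd"] == 0.0

    def test_overall_column_is_trial_mean_average(self):
        assert study.overall_from_trial_means((15.0, 7.5, 5.0)) == pytest.approx(
            9.1666, abs=1e-3
        )

    def test_between_cohort_contrasts_present(self, score_table):
        bundle = build_report(score_table)
        assert len(bundle.between_cohort) == 3
        assert {"mean_diff", "welch_t", "hedges_g", "d_av", "p"}.issubset(
            bundle.between_cohort.columns
        )

    def test_survey_sections(self, score_table, scored_surveys):
        bundle = build_report(score_table, scored_surveys)
        assert bundle.sus is not None
        overall = bundle.sus.set_index("cohort").loc["Overall", "sus_mean"]
        cohort_rows = bundle.sus[bundle.sus["cohort"] != "Overall"]
        expected = study.weighted_mean(
            dict(zip(cohort_rows["cohort"], cohort_rows["sus_mean"])),
            dict(zip(cohort_rows["cohort"], cohort_rows["n"])),
        )
        assert overall == pytest.approx(expected)
        assert set(bundle.tlx_pairwise) == {"performance", "temporal"}
        # no multiple-comparison adjustment anywhere
        for name, table in bundle.tlx_pairwise.items():
            assert not any("adjust" in c or "corrected" in c
                           for c in table.columns)

    def test_empty_surveys_degrade_gracefully(self, score_table):
        bundle = build_report(score_table, None)
        assert bundle.sus is None and bundle.tlx is None
        assert "survey sections absent" in bundle.warnings

    def test_missing_cohort_warns(self, score_table):
        partial = score_table[score_table["cohort"] != "A3"]
        with pytest.warns(UserWarning, match="missing cohorts"):
            bundle = build_report(partial)
        assert any("A3" in w for w in bundle.warnings)

    def test_write_report_round_trips(self, score_table, scored_surveys, tmp_path):
        bundle = build_report(score_table, scored_surveys)
        write_report(bundle, tmp_path)
        perf = pd.read_csv(tmp_path / "performance_by_cohort.csv")
        assert len(perf) == 4
        assert (tmp_path / "sus_by_cohort.csv").exists()
        assert (tmp_path / "tlx_pairwise_performance.csv").exists()
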