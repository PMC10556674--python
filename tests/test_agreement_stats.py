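"""Agreement suite: Bland–Altman internals, gated paired tests, Pearson, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietval import agreement_stats as ag
from dietval.errors import DomainError


def _pairs(a, b):
    a = np.asarray(a, dtype=float)
    return ag.PairedEstimates([f"P{i}" for i in range(a.size)], a, b)


class TestBlandAltman:
    def test_identical_methods(self):
        r = ag.bland_altman(_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert r.bias == 0.0 and r.sd_diff == 0.0
        assert r.loa == (0.0, 0.0)

    def test_symmetric_hand_case(self):
        r = ag.bland_altman(_pairs([0.0, 1.0, 2.0], [1.0, 1.0, 1.0]))
        assert r.bias == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa == (pytest.approx(-1.96), pytest.approx(1.96))

    def test_moments_reproduce_published_internals(self):
        """t-based CIs and SE LoA from the classical approximation."""
        r = ag.bland_altman_from_moments(-329.6, 599.1, 30)
        assert r.loa[0] == pytest.approx(-1503.8, abs=0.05)
        assert r.se_bias == pytest.approx(109.4, abs=0.05)
        assert r.bias_ci[0] == pytest.approx(-553.3, abs=0.05)
        r2 = ag.bland_altman_from_moments(-543.0, 642.6, 30)
        assert r2.loa == (pytest.approx(-1802.5, abs=0.05),
                          pytest.approx(716.5, abs=0.05))
        assert r2.se_loa == pytest.approx(203.2, abs=0.05)

    @given(st.lists(st.floats(-1000, 1000), min_size=3, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_internal_consistency(self, diffs):
        pairs = _pairs(diffs, np.zeros(len(diffs)))
        r = ag.bland_altman(pairs)
        assert r.loa[1] - r.loa[0] == pytest.approx(2 * 1.96 * r.sd_diff, rel=1e-12, abs=1e-12)
        assert r.se_bias * np.sqrt(r.n) == pytest.approx(r.sd_diff, rel=1e-12, abs=1e-12)
        assert r.se_loa == pytest.approx(r.sd_diff * np.sqrt(3.0 / r.n), rel=1e-12, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(DomainError):
            ag.bland_altman(_pairs([1.0], [2.0]))


class TestPairedDifferenceTest:
    def test_degenerate_zero_variance(self):
        r = ag.paired_difference_test(_pairs([5.0, 6.0, 7.0], [4.0, 5.0, 6.0]))
        assert r.test_used == "degenerate"
        assert r.p_raw is None and r.p_adj is None
        assert r.mean_difference == pytest.approx(1.0)

    def test_bonferroni_moves_p_across_alpha(self):
        """p=0.022 is significant raw but not after a 3x correction."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            d = rng.normal(0.6, 1.0, 25)
            r = ag.paired_difference_test(_pairs(d, np.zeros(25)), bonferroni_factor=3)
            if r.p_raw is not None and 0.01 < r.p_raw < 0.03:
                assert r.p_adj == pytest.approx(3 * r.p_raw)
                assert r.p_raw < 0.05 < r.p_adj
                return
        pytest.fail("no replicate landed in the target p range")

    def test_p_adjustment_capped_at_one(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.0, 1.0, 20)
        r = ag.paired_difference_test(_pairs(d, np.zeros(20)), bonferroni_factor=50)
        assert r.p_adj == 1.0

    def test_normality_gate_selects_wilcoxon(self):
        # heavy-tailed differences fail Shapiro–Wilk and route to Wilcoxon
        rng = np.random.default_rng(5)
        d = rng.standard_cauchy(40) + 0.5
        r = ag.paired_difference_test(_pairs(d, np.zeros(40)))
        assert r.shapiro_p < 0.05
        assert r.test_used == "wilcoxon"

    def test_normal_differences_use_t(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, 30)
        r = ag.paired_difference_test(_pairs(d, np.zeros(30)))
        assert r.shapiro_p >= 0.05
        assert r.test_used == "paired_t"


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = ag.pearson(_pairs(2 * x + 1, x))
        assert r.r == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_hand_value(self):
        r = ag.pearson(_pairs([2.0, 1.0, 3.0], [1.0, 2.0, 3.0]))
        assert r.r == pytest.approx(0.5)

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ag.pearson(_pairs(-x, x)).r == pytest.approx(-1.0)

    def test_agrees_with_brute_force_covariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=25)
            y = rng.normal(size=25) + 0.4 * x
            r = ag.pearson(_pairs(y, x)).r
            brute = (np.mean((x - x.mean()) * (y - y.mean()))
                     / (x.std(ddof=0) * y.std(ddof=0)))
            assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            ag.pearson(_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestICC:
    def test_distinct_constant_series_gives_one(self):
        daily = {"P1": [1000.0] * 5, "P2": [2000.0] * 5, "P3": [3000.0] * 5}
        r = ag.icc_random_intercept(daily)
        assert r.icc == pytest.approx(1.0)
        assert r.var_within == pytest.approx(0.0)

    def test_shared_mean_noise_gives_near_zero(self):
        rng = np.random.default_rng(21)
        daily = {f"P{i}": 2000.0 + rng.normal(0, 600, 7) for i in range(30)}
        assert ag.icc_random_intercept(daily).icc <= 0.05

    def test_parameter_recovery(self):
        """sigma_b^2=1, sigma_w^2=3: mean estimate within ±0.1 of 0.25."""
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(200):
            b = rng.normal(0.0, 1.0, 30)
            y = b[:, None] + rng.normal(0.0, np.sqrt(3.0), (30, 7))
            estimates.append(
                ag.icc_random_intercept({f"P{i}": y[i] for i in range(30)}).icc)
        assert np.mean(estimates) == pytest.approx(0.25, abs=0.1)

    def test_balanced_anova_matches_reml(self):
        """On balanced data the ANOVA path equals the REML path (cross-check)."""
        import pandas as pd
        rng = np.random.default_rng(33)
        b = rng.normal(0.0, 40.0, 12)
        rows = [(f"P{i}", v) for i in range(12)
                for v in b[i] + rng.normal(0.0, 60.0, 6)]
        daily = pd.DataFrame(rows, columns=["participant_id", "value"])
        anova = ag.icc_random_intercept(daily)
        assert anova.method == "anova"
        var_b, var_w = ag._icc_reml(daily)
        assert var_b / (var_b + var_w) == pytest.approx(anova.icc, abs=1e-4)

    def test_matches_pingouin_oneway_random(self):
        """Independent oracle: pingouin's ICC1 on the same long table."""
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(17)
        b = rng.normal(0.0, 300.0, 10)
        rows = [(f"P{i}", d, 2000.0 + b[i] + rng.normal(0.0, 500.0))
                for i in range(10) for d in range(7)]
        df = pd.DataFrame(rows, columns=["participant_id", "day", "value"])
        ours = ag.icc_random_intercept(df[["participant_id", "value"]])
        icc1 = pg.intraclass_corr(data=df, targets="participant_id",
                                  raters="day", ratings="value")
        ref = float(icc1["ICC"].iloc[0])  # first row: one-way random, single rater
        # on a balanced one-way layout the variance-ratio ICC equals ICC1
        assert ours.icc == pytest.approx(ref, abs=1e-6)

    def test_unbalanced_uses_reml(self):
        rng = np.random.default_rng(9)
        daily = {f"P{i}": 2000.0 + rng.normal(0, 300) + rng.normal(0, 400, 4 + i % 4)
                 for i in range(12)}
        r = ag.icc_random_intercept(daily)
        assert r.method == "reml"
        assert 0.0 <= r.icc <= 1.0

    def test_all_single_day_rejected(self):
        with pytest.raises(DomainError):
            ag.icc_random_intercept({"P1": [1.0], "P2": [2.0]})


class TestOverUnder:
    def test_uniform_underscaling(self):
        b = np.array([1000.0, 2000.0, 1500.0])
        s = ag.over_under_summary(_pairs(0.9 * b, b))
        assert s.n_under == 3 and s.n_over == 0
        assert s.mpd_overall == pytest.approx(-10.0)

    def test_hand_split(self):
        s = ag.over_under_summary(_pairs([1200.0, 800.0], [1000.0, 1000.0]))
        assert s.n_over == 1 and s.n_under == 1 and s.n_zero == 0
        assert s.mpd_over == pytest.approx(20.0)
        assert s.mpd_under == pytest.approx(-20.0)
        assert s.mpd_overall == pytest.approx(0.0)

    def test_exact_zero_counted_separately(self):
        b = np.array([1000.0, 1500.0])
        s = ag.over_under_summary(_pairs(b, b))
        assert s.n_zero == 2 and s.n_over == 0 and s.n_under == 0
        assert s.mpd_overall == 0.0

    def test_mpd_is_mean_of_individual_percentages(self):
        """MPD must be the mean of per-participant percentages, not the
        percentage difference of the means (brute-force loop oracle)."""
        rng = np.random.default_rng(14)
        a = rng.uniform(1200, 2600, 30)
        b = rng.uniform(1500, 3000, 30)
        s = ag.over_under_summary(_pairs(a, b))
        brute = sum(100.0 * (ai - bi) / bi for ai, bi in zip(a, b)) / 30
        pct_of_means = 100.0 * (a.mean() - b.mean()) / b.mean()
        assert s.mpd_overall == pytest.approx(brute, abs=1e-12)
        assert s.mpd_overall != pytest.approx(pct_of_means, abs=1e-6)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            ag.over_under_summary(_pairs([1.0, 2.0], [0.0, 2.0]))
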