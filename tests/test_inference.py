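"""Treatment-comparison statistics: ANOVA/Tukey/letters, rank-sum pairs,
proportion tests, loss-rate slopes, AICc selection, Spearman."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import marshcascade.inference as inf


class TestAnovaTukey:
    def test_identical_groups(self):
        cmp = inf.anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert cmp.statistic == 0.0 and cmp.p == 1.0

    def test_distant_group_gets_distinct_letter(self):
        cmp = inf.anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3],
                               "c": [101, 102, 103]})
        assert cmp.letters["a"] == cmp.letters["b"]
        assert not set(cmp.letters["c"]) & set(cmp.letters["a"])

    def test_pairwise_p_matches_studentized_range_oracle(self):
        # direct studentized-range computation on a 3-group toy
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(mu, 1.0, 6)
                  for g, mu in zip("abc", [0.0, 1.0, 2.5])}
        cmp = inf.anova_tukey(groups)
        arrays = list(groups.values())
        n, k = 6, 3
        dfe = k * n - k
        mse = np.sum([np.sum((a - a.mean()) ** 2) for a in arrays]) / dfe
        for _, row in cmp.pairwise.iterrows():
            d = abs(np.mean(groups[row["group1"]]) -
                    np.mean(groups[row["group2"]]))
            q = d / math.sqrt(mse / n)
            p_direct = stats.studentized_range.sf(q, k, dfe)
            assert row["p_adj"] == pytest.approx(p_direct, abs=1e-6)

    def test_label_permutation_permutes_letters(self):
        rng = np.random.default_rng(9)
        data = {g: rng.normal(mu, 1, 8)
                for g, mu in zip("abc", [0, 0.2, 4.0])}
        cmp1 = inf.anova_tukey(data)
        renamed = {"x": data["b"], "y": data["c"], "z": data["a"]}
        cmp2 = inf.anova_tukey(renamed)
        assert cmp1.letters["a"] == cmp2.letters["z"]
        assert cmp1.letters["b"] == cmp2.letters["x"]
        assert cmp1.letters["c"] == cmp2.letters["y"]

    def test_omnibus_only_skips_posthoc(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(0, 1, 8) for g in "abcd"}
        cmp = inf.anova_tukey(groups, posthoc=False)
        assert cmp.pairwise.empty
        f_direct, p_direct = stats.f_oneway(*groups.values())
        assert cmp.statistic == pytest.approx(f_direct)
        assert cmp.p == pytest.approx(p_direct)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            inf.anova_tukey({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="F undefined"):
            inf.anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestCompactLetterDisplay:
    def test_letters_encode_exactly_the_nonsignificant_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            k = rng.integers(3, 6)
            names = [f"g{i}" for i in range(k)]
            means = {g: float(rng.normal(0, 2)) for g in names}
            pairs = list(itertools.combinations(names, 2))
            sig = {frozenset(p) for p in pairs if rng.random() < 0.4}
            # transitive clashes are fine: the display must still separate
            # significant pairs and keep non-significant pairs together
            letters = inf.compact_letter_display(names, means, sig)
            for a, b in pairs:
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != (frozenset((a, b)) in sig)


class TestWilcoxonPairwise:
    def test_identical_groups_adjusted_one(self):
        cmp = inf.wilcoxon_pairwise({"a": [3.0] * 8, "b": [3.0] * 8,
                                     "c": [3.0] * 8})
        assert (cmp.pairwise["p_adj"] == 1.0).all()

    def test_bonferroni_is_m_times_raw(self):
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abc")}
        cmp = inf.wilcoxon_pairwise(groups)
        m = len(cmp.pairwise)
        for _, row in cmp.pairwise.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, m * row["p_raw"]))

    def test_exact_small_sample_against_enumeration(self):
        # n=4 vs 4, no ties: exact two-sided rank-sum p by full enumeration
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        cmp = inf.wilcoxon_pairwise({"a": a, "b": b})
        combined = np.concatenate([a, b])
        ranks = stats.rankdata(combined)
        observed = ranks[:4].sum()
        null = [sum(c) for c in itertools.combinations(ranks, 4)]
        null = np.array(null)
        mean_null = null.mean()
        p_exact = np.mean(np.abs(null - mean_null) >=
                          abs(observed - mean_null) - 1e-12)
        assert cmp.pairwise["p_raw"].iloc[0] == pytest.approx(p_exact)

    def test_large_shift_detected_at_n8(self):
        rng = np.random.default_rng(12)
        detected = 0
        for _ in range(200):
            a = rng.normal(0, 1, 8)
            b = rng.normal(3.0, 1, 8)
            cmp = inf.wilcoxon_pairwise({"a": a, "b": b})
            detected += cmp.pairwise["p_adj"].iloc[0] < 0.05
        assert detected / 200 > 0.95


class TestPairwiseProportions:
    def test_equal_proportions(self):
        cmp = inf.pairwise_proportions({"a": 10, "b": 10},
                                       {"a": 20, "b": 20})
        assert cmp.pairwise["p_adj"].iloc[0] == 1.0

    def test_extreme_difference(self):
        cmp = inf.pairwise_proportions({"a": 0, "b": 20},
                                       {"a": 20, "b": 20})
        assert cmp.pairwise["p_adj"].iloc[0] < 0.001

    def test_chi_square_oracle(self):
        cmp = inf.pairwise_proportions({"a": 5, "b": 15}, {"a": 30, "b": 30})
        chi2, p, _, _ = stats.chi2_contingency(
            [[5, 25], [15, 15]], correction=True)
        assert cmp.pairwise["p_raw"].iloc[0] == pytest.approx(p)

    def test_symmetry_under_arm_swap(self):
        p1 = inf.pairwise_proportions({"a": 4, "b": 12}, {"a": 20, "b": 20})
        p2 = inf.pairwise_proportions({"b": 12, "a": 4}, {"b": 20, "a": 20})
        assert p1.pairwise["p_raw"].iloc[0] == \
            pytest.approx(p2.pairwise["p_raw"].iloc[0])


class TestFirstWeekLossRate:
    def _frame(self, counts_by_plot):
        rows = []
        for plot, counts in counts_by_plot.items():
            for day, c in enumerate(counts):
                rows.append({"plot_id": plot, "treatment": "planting_control",
                             "day": day, "count": c})
        return pd.DataFrame(rows)

    def test_constant_counts_zero_slope(self):
        out = inf.first_week_loss_rate(self._frame({"p1": [50] * 8}))
        assert out["slope"].iloc[0] == pytest.approx(0.0)

    def test_exact_linear_decline(self):
        counts = [135 - 3 * d for d in range(8)]
        out = inf.first_week_loss_rate(self._frame({"p1": counts}))
        assert out["slope"].iloc[0] == pytest.approx(-3.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(8)
        counts = list(rng.poisson(100, 8))
        out = inf.first_week_loss_rate(self._frame({"p1": counts}))
        x = np.arange(8, dtype=float)
        y = np.array(counts, dtype=float)
        closed = np.sum((x - x.mean()) * (y - y.mean())) / \
            np.sum((x - x.mean()) ** 2)
        assert out["slope"].iloc[0] == pytest.approx(closed)


class TestModelSelection:
    def test_exactly_linear_selects_linear(self):
        x = np.linspace(0, 10, 20)
        fit = inf.fit_and_select(x, 2.0 + 0.5 * x)
        assert fit.form == "linear"

    def test_strong_curvature_selects_quadratic(self):
        rng = np.random.default_rng(3)
        x = np.linspace(-3, 3, 40)
        y = 1.0 + 0.2 * x + 2.0 * x**2 + rng.normal(0, 0.3, x.size)
        fit = inf.fit_and_select(x, y)
        assert fit.form == "quadratic"
        assert fit.candidates["quadratic"] < fit.candidates["linear"]

    def test_small_sample_correction_formula(self):
        # AICc - AIC = 2k(k+1)/(n-k-1); linear model has k=3 (b0, b1, s2)
        rng = np.random.default_rng(4)
        x = np.arange(8, dtype=float)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, 8)
        fit = inf.fit_and_select(x, y)
        coef = np.polyfit(x, y, 1)
        rss = float(np.sum((y - np.polyval(coef, x)) ** 2))
        n, k = 8, 3
        aic = 2 * k + n * (math.log(2 * math.pi * rss / n) + 1)
        expected = aic + 2 * k * (k + 1) / (n - k - 1)
        assert fit.candidates["linear"] == pytest.approx(expected, rel=1e-9)

    def test_correction_vanishes_with_n(self):
        rng = np.random.default_rng(5)
        for n, tol in ((30, 1.72), (3000, 0.017)):
            x = np.linspace(0, 1, n)
            y = x + rng.normal(0, 0.1, n)
            fit = inf.fit_and_select(x, y)
            coef = np.polyfit(x, y, 1)
            rss = float(np.sum((y - np.polyval(coef, x)) ** 2))
            aic = 2 * 3 + n * (math.log(2 * math.pi * rss / n) + 1)
            assert abs(fit.candidates["linear"] - aic) < tol


class TestSpearman:
    def test_self_correlation_one(self, function_matrix):
        rho = inf.spearman_matrix(function_matrix)
        assert np.allclose(np.diag(rho), 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        df1 = pd.DataFrame({"a": a, "b": b})
        df2 = pd.DataFrame({"a": np.exp(a), "b": b**3})
        assert inf.spearman_matrix(df1).loc["a", "b"] == pytest.approx(
            inf.spearman_matrix(df2).loc["a", "b"])

    def test_matches_rank_then_pearson(self, function_matrix):
        cols = list(function_matrix.select_dtypes("number").columns[:5])
        rho = inf.spearman_matrix(function_matrix, columns=cols)
        ranked = function_matrix[cols].rank()
        pearson = np.corrcoef(ranked.to_numpy(), rowvar=False)
        assert np.allclose(rho.to_numpy(), pearson, atol=1e-12)
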