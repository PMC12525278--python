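"""Group-comparison layer: test choice, exact Mann-Whitney, Kruskal-Wallis +
Dunn, ANOVA + Tukey, chi-square, significance stars."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from lysomorph.stats import (
    anova_tukey,
    chi_square_proportions,
    choose_test,
    kruskal_dunn,
    mann_whitney,
    stars,
    t_test,
)


class TestStars:
    @pytest.mark.parametrize("p,code", [
        (0.5, "ns"), (0.05, "ns"), (0.049, "*"), (0.01, "*"),
        (0.009, "**"), (0.001, "**"), (0.0009, "***"), (0.0, "***"),
    ])
    def test_bins(self, p, code):
        assert stars(p) == code

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stars(1.5)


class TestChooseTest:
    def test_two_gaussian_groups_t(self):
        rng = np.random.default_rng(0)
        samples = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)}
        assert choose_test(samples) == "t"

    def test_two_skewed_groups_mann_whitney(self):
        rng = np.random.default_rng(1)
        samples = {"a": rng.exponential(1, 40) ** 2, "b": rng.exponential(1, 40) ** 2}
        assert choose_test(samples) == "mann_whitney"

    def test_five_skewed_groups_kruskal(self):
        rng = np.random.default_rng(2)
        samples = {g: rng.lognormal(0, 1.2, 30) for g in "abcde"}
        assert choose_test(samples) == "kruskal_dunn"

    def test_three_gaussian_groups_anova(self):
        rng = np.random.default_rng(2)
        samples = {g: rng.normal(0, 1, 30) for g in "abc"}
        assert choose_test(samples) == "anova_tukey"

    def test_categorical_design(self):
        assert choose_test({}, design="categorical") == "chi_square"

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            choose_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


def permutation_oracle(a, b):
    """Exact two-sided p by enumerating group assignments, with U computed by
    direct pair counting (independent of the rank-sum implementation)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    n = len(pooled)

    def u_of(idx_a):
        set_a = set(idx_a)
        ua = 0.0
        for i in idx_a:
            for j in range(n):
                if j in set_a:
                    continue
                if pooled[i] > pooled[j]:
                    ua += 1.0
                elif pooled[i] == pooled[j]:
                    ua += 0.5
        return ua

    mu = n_a * (n - n_a) / 2.0
    obs = u_of(tuple(range(n_a)))
    dev = abs(obs - mu)
    count = sum(
        1 for idx in combinations(range(n), n_a) if abs(u_of(idx) - mu) >= dev - 1e-9
    )
    return count / comb(n, n_a)


class TestMannWhitney:
    def test_extreme_ranking_example(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 of the 20 assignments are this extreme
        assert res.test == "mann_whitney"

    def test_identical_samples_p_one(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_samples_too_small(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2], [3, 4, 5])

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (3, 4), (3, 5), (4, 4), (3, 6), (4, 5), (3, 7), (4, 6), (5, 5)])
    def test_exact_branch_equals_permutation_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(3):
            a = rng.integers(0, 6, n_a).astype(float)  # coarse grid: ties likely
            b = rng.integers(0, 6, n_b).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(permutation_oracle(a, b), abs=1e-12)

    def test_exact_branch_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 5)
            res = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_descriptives_present(self):
        res = mann_whitney([1, 2, 3, 4], [2, 3, 4, 5], groups=("CT", "PD"))
        assert res.descriptives["CT"]["n"] == 4
        assert res.descriptives["PD"]["median"] == pytest.approx(3.5)


class TestKruskalDunn:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 30)
        res = kruskal_dunn({"a": x, "b": x.copy(), "c": x.copy()})
        omnibus, pairwise = res[0], res[1:]
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-9)
        assert all(c.stars == "ns" for c in pairwise)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(11)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                  "c": rng.normal(15, 1, 30)}
        res = kruskal_dunn(groups)
        for c in res[1:]:
            if "c" in c.groups:
                assert c.p_value < 0.001
            else:
                assert c.p_value > 0.05

    def test_omnibus_h_matches_hand_ranks(self):
        """3 tie-free groups of 3: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        mean_ranks = {"a": 2.0, "b": 5.0, "c": 8.0}
        h_hand = 12.0 / (9 * 10) * sum(3 * (mean_ranks[g] - 5.0) ** 2 for g in groups)
        res = kruskal_dunn(groups)
        assert res[0].statistic == pytest.approx(h_hand)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})


class TestAnovaTukey:
    def test_f_matches_hand_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        grand = np.mean([x for g in groups.values() for x in g])
        ss_between = sum(3 * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        res = anova_tukey(groups)
        assert res[0].statistic == pytest.approx(f_hand)

    def test_shifted_pair_significant(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, 20)
        groups = {"a": base, "b": base + rng.normal(0, 1e-3, 20), "c": base + 10.0}
        res = anova_tukey(groups)
        for c in res[1:]:
            if "c" in c.groups:
                assert c.p_value < 0.001

    def test_mean_f_near_one_under_null(self):
        rng = np.random.default_rng(13)
        fs = [anova_tukey({g: rng.normal(0, 1, 10) for g in "abc"})[0].statistic
              for _ in range(100)]
        # E[F] = dfw/(dfw-2) = 27/25 = 1.08; simulation CI on the mean
        sem = np.std(fs, ddof=1) / 10.0
        assert abs(np.mean(fs) - 27 / 25) <= 3 * sem

    def test_zero_variance_everywhere_errors(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0] * 5, "b": [1.0] * 5, "c": [1.0] * 5})


class TestChiSquare:
    def test_identical_proportions_zero(self):
        res = chi_square_proportions(np.array([[20, 80], [20, 80]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.stars == "ns"

    def test_fragmentation_contrast_significant(self):
        # fragmented / unfragmented counts at the reported prevalences,
        # ~100 cells per group
        res = chi_square_proportions(np.array([[85, 18], [15, 87]]))
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_matches_hand_formula(self):
        table = np.array([[12, 30], [25, 9]])
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        res = chi_square_proportions(table)
        assert res.statistic == pytest.approx(chi2_hand)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square_proportions(np.array([[0, 0], [5, 5]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_square_proportions(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestTTest:
    def test_matches_scipy(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        res = t_test(a, b)
        ref = sps.ttest_ind(a, b)
        assert res.p_value == pytest.approx(float(ref.pvalue))
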