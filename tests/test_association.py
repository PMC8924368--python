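"""Tests of the cross-cutting statistics and the drug-sensitivity screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ticscore as ts


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        H, df, p = ts.kruskal_wallis([1, 2, 1, 2, 1, 2], ["a", "a", "b", "b", "c", "c"])
        assert H == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_hand_rank_sum_value(self):
        # groups {1,2}, {3,4}, {5,6}: H = 12/(6*7) * sum n_i (rbar_i - 3.5)^2
        H, df, p = ts.kruskal_wallis([1, 2, 3, 4, 5, 6], list("aabbcc"))
        assert H == pytest.approx(4.571, abs=1e-3)

    def test_all_constant_returns_null(self, caplog):
        with caplog.at_level("WARNING"):
            H, df, p = ts.kruskal_wallis([2.0] * 9, list("aaabbbccc"))
        assert H == 0.0 and p == 1.0

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        H_obs, _, p_asym = ts.kruskal_wallis(values, labels)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            H, _, _ = ts.kruskal_wallis(values, perm)
            count += H >= H_obs - 1e-12
        p_perm = count / n_perm
        assert abs(p_perm - p_asym) < 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02


class TestWilcoxonRanksum:
    def test_identical_multisets_p_one(self):
        W, p = ts.wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_one_sided_enumeration(self):
        # all of a below all of b: one-sided p = 1 / C(6,3) = 0.05
        W, p = ts.wilcoxon_ranksum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    def test_exact_and_asymptotic_branches_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=13)
            b = rng.normal(0.3, 1, size=13)
            _, p_exact = ts.wilcoxon_ranksum(a, b)  # n <= 25, no ties -> exact
            p_asym = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.wilcoxon_ranksum([], [1.0])


class TestChisq:
    def test_balanced_table_zero(self):
        chi2, df, p = ts.chisq_independence([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        chi2, df, p = ts.chisq_independence([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(6.667, abs=1e-3)
        assert df == 1

    def test_two_by_two_identity(self):
        a, b, c, d = 12, 5, 7, 16
        chi2, _, _ = ts.chisq_independence([[a, b], [c, d]])
        n = a + b + c + d
        ident = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(ident)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ts.chisq_independence([[0, 0], [3, 4]])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert ts.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert ts.spearman(x, -x**3)[0] == pytest.approx(-1.0)

    def test_hand_d_squared_formula(self):
        # 1..10 with two swapped neighbors: rho = 1 - 6*2 / (10*99)
        y = np.arange(1, 11, dtype=float)
        y[4], y[5] = y[5], y[4]
        rho, _ = ts.spearman(np.arange(1, 11, dtype=float), y)
        assert rho == pytest.approx(1 - 12 / 990, abs=1e-4)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ts.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ts.spearman([1, 2], [3, 4])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = ts.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_auc_equals_trapezoid_under_curve(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100).round(1)  # ties on purpose
        labels = rng.integers(0, 2, size=100)
        auc, curve = ts.roc_auc(scores, labels)
        area = np.trapezoid(curve["tpr"], curve["fpr"])
        assert auc == pytest.approx(area, abs=1e-9)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(100):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            if labels.min() == labels.max():
                continue
            aucs.append(ts.roc_auc(scores, labels)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        a1, _ = ts.roc_auc(scores, labels)
        a2, _ = ts.roc_auc(np.exp(scores * 2), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ts.roc_auc([1.0, 2.0], [1, 1])


class TestDrugScreen:
    def _screen_inputs(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=n),
                           index=[f"s{i}" for i in range(n)])
        auc = pd.DataFrame(
            {
                "linked": 1 / (1 + np.exp(scores.to_numpy() + rng.normal(0, 0.3, n))),
                "noise": rng.uniform(0.2, 0.8, n),
            },
            index=scores.index,
        )
        return scores, auc

    def test_threshold_is_strict_and_direction_checked(self):
        scores, auc = self._screen_inputs()
        res = ts.drug_screen(scores, auc, source_threshold=-0.20)
        assert bool(res.loc["linked", "passes"])
        assert not bool(res.loc["noise", "passes"])
        assert (res[res["passes"]]["rho"] < -0.20).all()

    def test_gdsc_threshold_stricter(self):
        scores, auc = self._screen_inputs(seed=1)
        res20 = ts.drug_screen(scores, auc, source_threshold=-0.20)
        res40 = ts.drug_screen(scores, auc, source_threshold=-0.40)
        assert res40["passes"].sum() <= res20["passes"].sum()

    def test_small_cohort_rejected(self):
        scores, auc = self._screen_inputs(n=15)
        with pytest.raises(ValueError):
            ts.drug_screen(scores, auc)

    def test_bad_decile_frac_rejected(self):
        scores, auc = self._screen_inputs()
        with pytest.raises(ValueError):
            ts.drug_screen(scores, auc, decile_frac=0.7)

    def test_planted_compound_recovery(self, signature):
        """Linked compounds recovered, independent ones not flagged."""
        good = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = ts.simulate_cohort(ts.CohortConfig(seed=500 + seed), signature)
            auc = ts.simulate_drug_response(
                cohort, n_compounds=12, n_linked=5, link_strength=0.7, seed=seed
            )
            # a faithful score stands in for the fitted one: the latent axis
            res = ts.drug_screen(cohort.latent_axis, auc, source_threshold=-0.20)
            hits = res["passes"]
            linked = [f"compound{c + 1:03d}" for c in range(5)]
            n_found = hits.loc[linked].sum()
            n_false = hits.drop(linked).sum()
            good += (n_found >= 4) and (n_false <= 1)
        assert good / n_seeds >= 0.9
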