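"""Rank tests, repeatability, collinearity screen, jackknifed LDA, exact tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import adjusted_rand_score

from eggsig import fidelity


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert fidelity.rank_sum_test([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)

    def test_exact_enumeration_oracle(self):
        # all 3 low vs all 3 high: one-sided 1/C(6,3) = 1/20, two-sided 0.1
        _, p = fidelity.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        _, p = fidelity.rank_sum_test(x, y)  # n1*n2 = 225 <= 400 -> exact branch
        asym = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(exact, abs=1e-12)
        assert abs(p - asym) < 0.02

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = fidelity.rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fidelity.rank_sum_test([], [1.0])


class TestIcc:
    def test_identical_within_distinct_between(self):
        vals = [1, 1, 1, 5, 5, 5, 9, 9, 9]
        groups = list("aaabbbccc")
        res = fidelity.icc(vals, groups)
        assert res.icc == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_no_between_group_signal(self):
        res = fidelity.icc([1, 2, 1, 2, 1, 2], list("aabbcc"))
        assert res.icc <= 0.0

    def test_balanced_variance_component_oracle(self):
        # sigma2_b = 3 sigma2_w -> true ICC = 0.75
        rng = np.random.default_rng(6)
        g = np.repeat(np.arange(100), 3)
        vals = np.sqrt(3.0) * rng.normal(size=100)[g] + rng.normal(size=300)
        res = fidelity.icc(vals, g)
        assert res.icc == pytest.approx(0.75, abs=0.07)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            fidelity.icc([1.0, 2.0, 3.0], list("abc"))


class TestCollinearityScreen:
    def test_orthogonal_traits_all_retained(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert fidelity.collinearity_screen(df) == list("abcd")

    def test_duplicated_trait_drops_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        kept = fidelity.collinearity_screen(df)
        assert "c" in kept and len(kept) == 2
        assert ("a" in kept) != ("b" in kept)

    def test_single_correlated_pair_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=500)
        c = rng.normal(size=500)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        kept = fidelity.collinearity_screen(df, threshold=0.7)
        assert len(kept) == 2 and "c" in kept


class TestLdaJackknife:
    def test_separated_clouds_near_perfect(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(10, 1, (80, 3))])
        y = np.repeat(["a", "b"], 80)
        res = fidelity.lda_jackknife(x, y)
        assert all(rate >= 0.99 for rate in res.correct_rates.values())
        assert res.confusion.sum() == 160

    def test_identical_distributions_chance_level(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(400, 4))
        y = np.repeat(["a", "b"], 200)
        res = fidelity.lda_jackknife(x, y)
        for rate in res.correct_rates.values():
            assert rate == pytest.approx(0.5, abs=0.08)

    def test_matches_brute_force_loo_oracle(self):
        # independent oracle: leave-one-out assignment from class means and
        # pooled covariance computed directly
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(1.5, 1, (15, 2))])
        y = np.repeat([0, 1], 15)
        res = fidelity.lda_jackknife(x, y)
        confusion = np.zeros((2, 2), dtype=int)
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            xk, yk = x[keep], y[keep]
            m0, m1 = xk[yk == 0].mean(axis=0), xk[yk == 1].mean(axis=0)
            s = np.zeros((2, 2))
            for c, m in ((0, m0), (1, m1)):
                d = xk[yk == c] - m
                s += d.T @ d
            s /= len(yk) - 2
            inv = np.linalg.inv(s)
            d0 = (x[i] - m0) @ inv @ (x[i] - m0)
            d1 = (x[i] - m1) @ inv @ (x[i] - m1)
            confusion[y[i], int(d1 < d0)] += 1
        assert np.array_equal(res.confusion, confusion)

    def test_agrees_with_sklearn_on_resubstitution_boundary(self):
        # cross-check the discriminant direction against sklearn's LDA
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(1, 1, (60, 3))])
        y = np.repeat([0, 1], 60)
        res = fidelity.lda_jackknife(x, y)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(x, y)
        cos = np.dot(res.coefficients, sk.coef_[0]) / (
            np.linalg.norm(res.coefficients) * np.linalg.norm(sk.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_outlier_filter_records_removals(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(3, 1, (50, 2))])
        x[0] = [50.0, -50.0]  # gross outlier
        y = np.repeat([0, 1], 50)
        res = fidelity.lda_jackknife(x, y, outlier_filter=True)
        assert 0 in res.outliers_removed
        assert res.confusion.sum() == 100 - len(res.outliers_removed)

    def test_jackknife_not_more_optimistic_than_resubstitution(self):
        rng = np.random.default_rng(8)
        gaps = []
        for _ in range(20):
            x = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(0.8, 1, (25, 3))])
            y = np.repeat([0, 1], 25)
            res = fidelity.lda_jackknife(x, y)
            jk_acc = np.trace(res.confusion) / res.confusion.sum()
            means, inv = fidelity._lda_discriminant(x, y, np.unique(y))
            resub = (fidelity._lda_assign(x, means, inv) == y).mean()
            gaps.append(resub - jk_acc)
        assert np.mean(gaps) >= 0.0


class TestConfusionExactTest:
    def test_balanced_table(self):
        orat, p = fidelity.confusion_exact_test([[10, 10], [10, 10]])
        assert orat == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_hypergeometric_enumeration(self):
        _, p = fidelity.confusion_exact_test([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            t = rng.integers(0, 20, (2, 2))
            _, p1 = fidelity.confusion_exact_test(t)
            _, p2 = fidelity.confusion_exact_test(t.T)
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_margin_uninformative(self):
        orat, p = fidelity.confusion_exact_test([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(orat)


class TestMorphCluster:
    def test_recovers_separated_morphs(self):
        rng = np.random.default_rng(10)
        centres = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        truth = np.repeat(np.arange(4), 40)
        x = centres[truth] + rng.normal(0, 0.5, (160, 2))
        labels = fidelity.morph_cluster(x, k=4, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_k_one_single_label(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        assert np.unique(fidelity.morph_cluster(x, k=1)).size == 1

    def test_seeded_determinism(self):
        x = np.random.default_rng(1).normal(size=(50, 3))
        l1 = fidelity.morph_cluster(x, k=4, seed=5)
        l2 = fidelity.morph_cluster(x, k=4, seed=5)
        assert np.array_equal(l1, l2)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            fidelity.morph_cluster(np.zeros((3, 2)), k=5)
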