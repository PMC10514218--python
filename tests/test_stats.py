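"""ROC/AUC, Youden cut-offs, DeLong, and classical group tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import agenorm as ag
from agenorm.errors import DegenerateStatisticError, ParameterError


def brute_force_auc(scores, labels):
    """Exhaustive pairwise Mann-Whitney probability (independent oracle)."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        scores = [0, 1, 2, 5, 6, 7]
        labels = [0, 0, 0, 1, 1, 1]
        assert ag.auc_mann_whitney(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert ag.auc_mann_whitney([3] * 8, [0] * 4 + [1] * 4) == 0.5

    def test_matches_exhaustive_pairwise_oracle_exactly(self, rng):
        for _ in range(50):
            n_pos = int(rng.integers(2, 20))
            n_neg = int(rng.integers(2, 20))
            # integer scores force ties so the 1/2 convention is exercised
            scores = rng.integers(0, 10, size=n_pos + n_neg).astype(float)
            labels = np.array([1] * n_pos + [0] * n_neg)
            assert ag.auc_mann_whitney(scores, labels) == brute_force_auc(scores, labels)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert ag.auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_complement_under_score_negation(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30)  # continuous: ties have probability 0
        labels = np.array([1] * 12 + [0] * 18)
        a = ag.auc_mann_whitney(scores, labels)
        b = ag.auc_mann_whitney(-scores, labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            ag.auc_mann_whitney([1, 2, 3], [1, 1, 1])


class TestOptimalCutoff:
    def test_midpoint_between_separated_groups(self):
        cutoff, sens, spec = ag.optimal_cutoff(
            [0, 1, 2, 5, 6], [0, 0, 0, 1, 1]
        )
        assert cutoff == 3.5 and sens == 1.0 and spec == 1.0

    def test_degenerate_identical_scores(self):
        cutoff, sens, spec = ag.optimal_cutoff([4] * 6, [0, 0, 0, 1, 1, 1])
        # J = 0 everywhere; the higher-specificity operating point wins
        assert sens + spec - 1.0 == 0.0
        assert spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        """Returned J equals the max J over every candidate cut-off."""
        for _ in range(20):
            scores = rng.integers(0, 30, size=50).astype(float)
            labels = rng.integers(0, 2, size=50)
            labels[:2] = [0, 1]
            cutoff, sens, spec = ag.optimal_cutoff(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            best = -np.inf
            for c in np.concatenate([np.unique(scores) - 0.5, [scores.max() + 0.5]]):
                best = max(best, (pos > c).mean() + (neg <= c).mean() - 1.0)
            assert sens + spec - 1.0 == pytest.approx(best, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.integers(0, 50, size=40).astype(float)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        c1, s1, p1 = ag.optimal_cutoff(scores, labels)
        c2, s2, p2 = ag.optimal_cutoff(np.exp(scores / 10), labels)
        assert (s1, p1) == (s2, p2)
        # the cut-offs delimit the same subjects
        assert ((scores > c1) == (np.exp(scores / 10) > c2)).all()

    def test_half_integer_cutoffs_on_integer_scores(self, rng):
        scores = rng.integers(0, 200, size=60).astype(float)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        cutoff, _, _ = ag.optimal_cutoff(scores, labels)
        assert cutoff % 0.5 == 0 and cutoff % 1 != 0


class TestDeLong:
    def test_identical_scores_degenerate(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([1] * 15 + [0] * 25)
        res = ag.delong_test(scores, scores.copy(), labels)
        assert res.degenerate and res.p == 1.0
        assert res.auc_a == res.auc_b

    def test_single_auc_variance_close_to_hanley_mcneil(self, rng):
        """DeLong variance of one AUC agrees with the Hanley-McNeil
        exponential-model approximation within 15% on exponential scores."""
        n = 50
        pos = rng.exponential(2.0, size=n) + 1.0
        neg = rng.exponential(1.0, size=n)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n + [0] * n)
        auc, var = ag.auc_variance_delong(scores, labels)
        q1 = auc / (2 - auc)
        q2 = 2 * auc ** 2 / (1 + auc)
        hm = (auc * (1 - auc) + (n - 1) * (q1 - auc ** 2) + (n - 1) * (q2 - auc ** 2)) / n ** 2
        assert var == pytest.approx(hm, rel=0.15)

    def test_null_p_values_uniform(self):
        """Under the null (two equally informative noisy score sets), DeLong
        p-values are uniform: KS test over 500 simulations."""
        r = np.random.default_rng(2024)
        pvals = []
        labels = np.array([1] * 30 + [0] * 30)
        signal = np.concatenate([np.ones(30), np.zeros(30)])
        for _ in range(500):
            a = signal + r.normal(0, 1.5, size=60)
            b = signal + r.normal(0, 1.5, size=60)
            pvals.append(ag.delong_test(a, b, labels).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_true_auc_difference(self):
        """With true AUCs ~0.9 vs ~0.7 at n=30+30, the test rejects far more
        often than alpha (power check against a bootstrap-free benchmark)."""
        r = np.random.default_rng(99)
        labels = np.array([1] * 30 + [0] * 30)
        signal = np.concatenate([np.ones(30), np.zeros(30)])
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = signal + r.normal(0, 0.55, size=60)   # AUC ~ 0.9
            b = signal + r.normal(0, 1.35, size=60)   # AUC ~ 0.7
            if ag.delong_test(a, b, labels).p < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            ag.delong_test([1, 2], [1, 2, 3], [0, 1])


class TestTwoSampleT:
    def test_equal_groups_give_t_zero_p_one(self):
        t, df, p = ag.two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_discovery_age_comparison_rounds_to_printed_p(self):
        """Discovery-sample ages: CN 73.45±5.75 (n=131) vs MCI 70.84±7.50 (n=91)."""
        _, _, p = ag.two_sample_t(73.45, 5.75, 131, 70.84, 7.50, 91, variant="pooled")
        assert round(p, 3) == 0.004

    def test_validation_age_comparison_rounds_to_printed_p(self):
        """CN 68.53±3.04 vs MCI 72.78±3.91 (n=19 each), pooled t-test."""
        _, _, p = ag.two_sample_t(68.53, 3.04, 19, 72.78, 3.91, 19, variant="pooled")
        assert round(p, 3) == 0.001

    def test_raw_sample_entry_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        t, df, p = ag.two_sample_t(x=x, y=y, variant="welch")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            ag.two_sample_t(5.0, 0.0, 10, 5.0, 0.0, 10)


class TestWilcoxonRankSum:
    def test_identical_multisets_p_one(self):
        x = np.arange(20, dtype=float)
        u, p = ag.wilcoxon_rank_sum(x, x.copy())
        assert p == 1.0

    def test_small_sample_exact_enumeration(self):
        """x={1,2}, y={3,4}: 2 of the C(4,2)=6 rank assignments are as
        extreme, so the exact two-sided p is 1/3."""
        _, p = ag.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_approximation_close_to_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(0.4, 1.0, 50)
        _, p = ag.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        obs = ranks[:50].sum()
        perm = np.array([
            rng.permutation(ranks)[:50].sum() for _ in range(20000)
        ])
        p_perm = np.mean(np.abs(perm - ranks.sum() / 2) >= abs(obs - ranks.sum() / 2))
        assert abs(p - p_perm) < 0.01

    def test_matches_scipy_asymptotic_with_ties(self, rng):
        x = rng.integers(0, 8, 30).astype(float)
        y = rng.integers(1, 9, 35).astype(float)
        u, p = ag.wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestChiSquare:
    def test_validation_gender_table_rounds_to_printed_p(self):
        """Gender 14/5 (CN) vs 11/8 (MCI): Pearson chi-square p = 0.305."""
        chi2, p = ag.chi_square_2x2([[14, 5], [11, 8]])
        assert round(p, 3) == 0.305

    def test_balanced_table_chi2_zero(self):
        chi2, p = ag.chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form_matches_scipy(self, rng):
        for _ in range(20):
            t = rng.integers(1, 40, size=(2, 2))
            chi2, p = ag.chi_square_2x2(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            ag.chi_square_2x2([[0, 0], [5, 5]])


class TestBonferroni:
    def test_grid_of_216_comparisons(self):
        """Per-test alpha 0.0001 over the 6x3x4x3 grid gives family-wise 0.0216."""
        assert ag.bonferroni_alpha(0.0001, 216) == pytest.approx(0.0216)

    def test_identity_for_single_comparison(self):
        assert ag.bonferroni_alpha(0.03, 1) == 0.03

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 0.5), st.integers(1, 500), st.integers(1, 500))
    def test_monotone_in_m_and_capped(self, alpha, m1, m2):
        lo, hi = sorted((m1, m2))
        assert ag.bonferroni_alpha(alpha, lo) <= ag.bonferroni_alpha(alpha, hi) <= 1.0
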