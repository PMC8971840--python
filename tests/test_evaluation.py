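"""Statistics oracles: brute-force AUC, hypergeometric Fisher enumeration,
bootstrap/permutation checks of the DeLong machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petlung.evaluation import (
    PredictionSet,
    SummaryStats,
    chi_square_2x2,
    delong_test,
    fisher_exact,
    metrics_from_counts,
    roc_auc,
    threshold_metrics,
    ttest_from_summary,
)


def brute_force_auc(labels, scores):
    """All-pairs Mann-Whitney probability, ties counted 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_fisher(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def _pset(labels, scores):
    ids = tuple(f"c{i}" for i in range(len(labels)))
    return PredictionSet(ids, np.asarray(labels), np.asarray(scores))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc(_pset([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]))
        assert res.auc == 1.0
        assert res.ci_low <= res.auc <= res.ci_high

    def test_all_ties_gives_half(self):
        res = roc_auc(_pset([0, 1, 0, 1], [0.5] * 4))
        assert res.auc == 0.5

    def test_small_example_by_pair_counting(self):
        labels = [1, 1, 1, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.3]
        res = roc_auc(_pset(labels, scores))
        assert res.auc == pytest.approx(brute_force_auc(labels, scores))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 1, n), 2)  # coarse grid induces ties
            got = roc_auc(_pset(labels, scores)).auc
            assert got == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.uniform(0, 1, 60)
        a = roc_auc(_pset(labels, scores)).auc
        b = roc_auc(_pset(1 - labels, scores)).auc
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_pset([1, 1], [0.5, 0.6]))


class TestThresholdMetrics:
    def test_reconstructed_cohort_counts(self):
        # confusion counts that reproduce the printed cohort metrics
        sens, spec, acc = metrics_from_counts(tp=71, fn=8, tn=18, fp=15)
        assert round(sens, 3) == 0.899
        assert round(spec, 3) == 0.545
        assert round(acc, 3) == 0.795

    def test_threshold_zero_catches_all_positives(self):
        sens, _, _ = threshold_metrics(_pset([1, 1, 0], [0.0, 0.9, 0.1]), 0.0)
        assert sens == 1.0

    def test_threshold_above_one_rejects_all(self):
        _, spec, _ = threshold_metrics(_pset([1, 0, 0], [0.9, 0.8, 0.2]), 1.5)
        assert spec == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_accuracy_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.uniform(0, 1, n)
        preds = _pset(labels, scores)
        sens, spec, acc = threshold_metrics(preds, 0.5)
        n_pos, n_neg = labels.sum(), n - labels.sum()
        assert acc == pytest.approx((sens * n_pos + spec * n_neg) / n)


def test_youden_threshold_maximizes_j():
    from petlung.evaluation import youden_threshold

    preds = _pset([0, 0, 0, 1, 1, 1], [0.1, 0.2, 0.6, 0.55, 0.8, 0.9])
    t = youden_threshold(preds)
    sens, spec, _ = threshold_metrics(preds, t)
    best_j = sens + spec - 1
    for other in np.linspace(0, 1, 101):
        s2, p2, _ = threshold_metrics(preds, other)
        assert s2 + p2 - 1 <= best_j + 1e-12


class TestDelong:
    def test_identical_predictions_p_one(self):
        a = _pset([0, 1, 0, 1, 1], [0.2, 0.7, 0.4, 0.9, 0.6])
        auc_a, auc_b, p = delong_test(a, a)
        assert auc_a == auc_b
        assert p == 1.0

    def test_case_mismatch_rejected(self):
        a = _pset([0, 1], [0.2, 0.7])
        b = PredictionSet(("x", "y"), np.array([0, 1]), np.array([0.3, 0.6]))
        with pytest.raises(ValueError):
            delong_test(a, b)

    def test_agrees_with_paired_bootstrap(self):
        """DeLong p within 0.02 of a 2000-rep paired bootstrap of the AUC
        difference on a fixed seeded dataset."""
        rng = np.random.default_rng(123)
        n = 80
        labels = np.array([1] * 40 + [0] * 40)
        latent = labels * 1.0 + rng.normal(0, 1.2, n)
        scores_a = 1 / (1 + np.exp(-(latent + rng.normal(0, 0.6, n))))
        scores_b = 1 / (1 + np.exp(-(latent + rng.normal(0, 0.9, n))))
        pa, pb = _pset(labels, scores_a), _pset(labels, scores_b)
        _, _, p_delong = delong_test(pa, pb)

        obs = roc_auc(pa).auc - roc_auc(pb).auc
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(set(labels[idx])) < 2:
                continue
            boots.append(
                brute_force_auc(labels[idx], scores_a[idx])
                - brute_force_auc(labels[idx], scores_b[idx])
            )
        boots = np.array(boots)
        se = boots.std(ddof=1)
        from scipy import stats as sps

        p_boot = float(2 * sps.norm.sf(abs(obs) / se))
        assert abs(p_delong - p_boot) < 0.02

    def test_type_i_error_calibrated_under_permutation_null(self):
        """Swapping the two score sets case-wise at random (null: same AUC)
        gives rejection rate within 2 SE of 0.05."""
        rng = np.random.default_rng(5)
        n = 60
        labels = np.array([1] * 30 + [0] * 30)
        latent = labels + rng.normal(0, 1, n)
        s1 = latent + rng.normal(0, 0.5, n)
        s2 = latent + rng.normal(0, 0.5, n)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            swap = rng.integers(0, 2, n).astype(bool)
            a = np.where(swap, s1, s2)
            b = np.where(swap, s2, s1)
            _, _, p = delong_test(_pset(labels, a), _pset(labels, b))
            rejections += p < 0.05
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2.5 * se + 0.01


class TestSummaryStatistics:
    @pytest.mark.parametrize(
        "a,b,expected_p",
        [
            ((33, 58.55, 13.31), (79, 63.84, 11.60), 0.038),  # age
            ((33, 24.88, 16.49), (79, 29.86, 18.99), 0.192),  # nodule diameter
            ((33, 2.97, 3.30), (79, 5.20, 3.80), 0.004),  # early SUVmax
        ],
    )
    def test_cohort_table_rows(self, a, b, expected_p):
        t, df, p = ttest_from_summary(SummaryStats(*a), SummaryStats(*b))
        assert df == a[0] + b[0] - 2
        assert round(p, 3) == expected_p

    def test_identical_groups(self):
        s = SummaryStats(10, 5.0, 1.0)
        t, _, p = ttest_from_summary(s, s)
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_convention(self):
        a = SummaryStats(5, 1.0, 0.0)
        assert ttest_from_summary(a, SummaryStats(5, 1.0, 0.0))[2] == 1.0
        assert ttest_from_summary(a, SummaryStats(5, 2.0, 0.0))[2] == 0.0


class TestCategorical:
    def test_balanced_table_chi2_zero(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 9], [11, 3]],
            [[4, 1], [20, 21]],
            [[21, 12], [39, 40]],
            [[5, 0], [1, 4]],
            [[29, 4], [67, 12]],
        ],
    )
    def test_fisher_matches_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(brute_force_fisher(table), abs=1e-9)

    def test_fisher_defined_with_zero_marginal(self):
        assert fisher_exact([[0, 0], [5, 5]]) == 1.0
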