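"""Evaluation metrics against independent oracles (closed forms,
exhaustive concordance, scikit-learn)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alvedef.metrics import (
    AgreementStats,
    ConfusionCounts,
    bland_altman,
    classification_stats,
    cohen_kappa,
    keypoint_stats,
    length_stats,
    match_keypoints,
    roc_auc,
)


class TestClassificationStats:
    def test_worked_example(self):
        stats = classification_stats(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert stats["accuracy"] == pytest.approx(0.8)
        assert stats["recall"] == pytest.approx(0.75)
        assert stats["precision"] == pytest.approx(0.75)
        assert stats["specificity"] == pytest.approx(5 / 6)
        assert stats["f1"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        stats = classification_stats(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(stats[k] == 1.0 for k in stats)

    def test_zero_recall(self):
        stats = classification_stats(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert stats["recall"] == 0.0
        assert stats["precision"] is None  # no positive predictions
        assert stats["f1"] is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            classification_stats(ConfusionCounts())

    def test_matches_bruteforce_on_10000_random_counts(self):
        """Definitions hold against label-vector reconstruction + sklearn."""
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(99)
        checked_with_sklearn = 0
        for _ in range(10_000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 30, 4))
            if tp + tn + fp + fn == 0:
                continue
            counts = ConfusionCounts(tp, tn, fp, fn)
            stats = classification_stats(counts)
            total = tp + tn + fp + fn
            assert stats["accuracy"] == pytest.approx((tp + tn) / total)
            if tp + fn:
                assert stats["recall"] == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert stats["precision"] == pytest.approx(tp / (tp + fp))
            if tn + fp:
                assert stats["specificity"] == pytest.approx(tn / (tn + fp))
            if stats["precision"] not in (None, 0) or stats["recall"] not in (None, 0):
                p, r = stats["precision"], stats["recall"]
                if p is not None and r is not None and p + r > 0:
                    assert stats["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)
            # spot-check against sklearn on reconstructed label vectors
            if checked_with_sklearn < 200:
                truth = [1] * tp + [1] * fn + [0] * tn + [0] * fp
                pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
                assert stats["accuracy"] == pytest.approx(accuracy_score(truth, pred))
                if tp + fn:
                    assert stats["recall"] == pytest.approx(recall_score(truth, pred))
                if tp + fp:
                    assert stats["precision"] == pytest.approx(
                        precision_score(truth, pred, zero_division=np.nan), nan_ok=True
                    )
                if stats["f1"] is not None:
                    assert stats["f1"] == pytest.approx(f1_score(truth, pred))
                checked_with_sklearn += 1


def auc_concordance_oracle(scores, labels):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_worked_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_concordance_oracle_up_to_n12(self):
        rng = np.random.default_rng(4)
        for _ in range(400):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.uniform(0, 1, n), 1)  # induce ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_concordance_oracle(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(50)	:
            n = int(rng.integers(5, 40))
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            scores = rng.uniform(0, 1, n)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)


class TestKeypoints:
    def test_counting_example(self):
        truth = [((i, "A"), 0.0, 0.0) for i in range(3)]
        pred = [((0, "A"), 0.3, 0.0), ((1, "A"), 0.5, 0.0), ((2, "A"), 2.5, 0.0)]
        rate, dists = match_keypoints(pred, truth, tolerance_mm=2.0)
        assert rate == pytest.approx(2 / 3)
        assert sorted(dists) == pytest.approx([0.3, 0.5])

    def test_no_predictions(self):
        truth = [((0, "A"), 1.0, 1.0)]
        rate, dists = match_keypoints([], truth, 2.0)
        assert rate == 0.0 and dists.size == 0

    def test_perfect_predictions(self):
        truth = [((i, "B"), float(i), 0.0) for i in range(5)]
        rate, dists = match_keypoints(truth, truth, 2.0)
        assert rate == 1.0
        assert np.allclose(dists, 0.0)

    def test_quartiles_linear_interpolation(self):
        stats = keypoint_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert stats.median_mm == pytest.approx(2.5)
        assert stats.q1_mm == pytest.approx(1.75)
        assert stats.q3_mm == pytest.approx(3.25)

    def test_single_distance(self):
        stats = keypoint_stats(np.array([5.0]))
        assert stats.aed_mm == 5.0
        assert stats.sd_mm == 0.0

    def test_equal_distances(self):
        stats = keypoint_stats(np.full(7, 0.4))
        assert stats.sd_mm == pytest.approx(0.0, abs=1e-12)
        assert stats.q1_mm == stats.median_mm == stats.q3_mm == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            keypoint_stats(np.array([]))


class TestLengthStats:
    def test_exact_predictions(self):
        stats = length_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (stats.mae, stats.rmse, stats.mre) == (0.0, 0.0, 0.0)
        assert stats.pcc == pytest.approx(1.0)

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 4.0])
        stats = length_stats(y + 0.5, y)
        assert stats.mae == pytest.approx(0.5)
        assert stats.rmse == pytest.approx(0.5)
        assert stats.pcc == pytest.approx(1.0)

    def test_anticorrelated(self):
        stats = length_stats([2.0, 1.0], [1.0, 2.0])
        assert stats.pcc == pytest.approx(-1.0)
        assert stats.mae == pytest.approx(1.0)

    @given(st.integers(2, 30), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_rmse_dominates_mae(self, n, seed):
        rng = np.random.default_rng(seed)
        true = rng.uniform(0.5, 6.0, n)
        pred = true + rng.normal(0, 1, n)
        stats = length_stats(pred, true)
        assert stats.rmse >= stats.mae - 1e-12


class TestBlandAltman:
    def test_identical_measurements(self):
        stats = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stats == AgreementStats(0.0, 0.0, 0.0, 0.0)

    def test_constant_difference(self):
        stats = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert stats.bias == pytest.approx(1.0)
        assert stats.loa_low == pytest.approx(1.0)
        assert stats.loa_high == pytest.approx(1.0)

    def test_symmetric_differences(self):
        stats = bland_altman([0.0, 2.0], [1.0, 1.0])  # differences -1, +1
        sd = np.std([-1.0, 1.0], ddof=1)
        assert stats.bias == pytest.approx(0.0)
        assert stats.loa_high == pytest.approx(1.96 * sd)
        assert stats.loa_low == pytest.approx(-1.96 * sd)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 5, 20), rng.uniform(0, 5, 20)
        stats = bland_altman(a, b)
        assert stats.loa_low <= stats.bias <= stats.loa_high

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(0, 2, 30)
            b = np.where(rng.uniform(size=30) < 0.8, a, 1 - a)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
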