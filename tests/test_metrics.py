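"""Evaluation metrics and fold assignment against brute-force oracles."""

import numpy as np
import pytest
import scipy.stats

from synergraph import (classification_metrics, mse_confidence_interval,
                        regression_metrics, stratified_kfold)


# -- brute-force oracles ---------------------------------------------------

def auc_all_pairs(labels, scores):
    """Mann-Whitney AUC with midrank tie handling, by exhaustive pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_step(labels, scores):
    """Precision-recall step integration over every distinct threshold
    (tied scores enter the curve together)."""
    ap, prev_recall = 0.0, 0.0
    for t in np.unique(scores)[::-1]:
        preds = scores >= t
        tp = np.sum(preds & (labels == 1))
        precision = tp / preds.sum()
        recall = tp / (labels == 1).sum()
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def kappa_confusion(labels, preds):
    n = len(labels)
    po = np.mean(labels == preds)
    pe = ((labels == 1).mean() * (preds == 1).mean()
          + (labels == 0).mean() * (preds == 0).mean())
    return (po - pe) / (1 - pe)


class TestStratifiedKFold:
    def test_even_split_single_stratum(self):
        folds = stratified_kfold(["x"] * 20, k=10, seed=0)
        sizes = np.bincount(folds.assignment, minlength=10)
        assert (sizes == 2).all()

    def test_seed_reproducible(self):
        strata = ["a"] * 30 + ["b"] * 15
        f1 = stratified_kfold(strata, k=5, seed=3)
        f2 = stratified_kfold(strata, k=5, seed=3)
        np.testing.assert_array_equal(f1.assignment, f2.assignment)

    def test_class_proportions_balanced(self, rng):
        strata = rng.choice(["syn", "add", "ant"], p=[0.2, 0.5, 0.3], size=200)
        folds = stratified_kfold(strata, k=10, seed=1)
        for cls in ("syn", "add", "ant"):
            per_fold = np.bincount(folds.assignment[strata == cls], minlength=10)
            assert per_fold.max() - per_fold.min() <= 1

    def test_small_stratum_merged_with_warning(self):
        strata = ["big"] * 40 + ["tiny"] * 3
        with pytest.warns(UserWarning, match="merged"):
            folds = stratified_kfold(strata, k=10, seed=0)
        assert len(folds.assignment) == 43
        assert folds.train_test(0)[1].size >= 4

    def test_partition(self):
        folds = stratified_kfold(["a"] * 23 + ["b"] * 30, k=4, seed=9)
        train, test = folds.train_test(2)
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(53))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mse == 0 and m.rmse == 0 and m.pcc == pytest.approx(1.0)

    def test_exact_arithmetic(self):
        m = regression_metrics([0, 1, 2], [2, 1, 0])
        assert m.mse == pytest.approx(8 / 3)
        assert m.pcc == pytest.approx(-1.0)

    def test_matches_loop_oracle(self, rng):
        y = rng.standard_normal(50)
        yh = rng.standard_normal(50)
        m = regression_metrics(y, yh)
        mse = sum((a - b) ** 2 for a, b in zip(y, yh)) / 50
        assert abs(m.mse - mse) < 1e-12
        assert abs(m.rmse - np.sqrt(mse)) < 1e-12
        yc, yhc = y - y.mean(), yh - yh.mean()
        pcc = (yc @ yhc) / np.sqrt((yc @ yc) * (yhc @ yhc))
        assert abs(m.pcc - pcc) < 1e-12

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = regression_metrics([1.0, 1.0], [0.0, 2.0])
        assert not m.pcc_defined and np.isnan(m.pcc)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0, 2.0])


class TestConfidenceInterval:
    def test_identical_folds_zero_width(self):
        lo, hi = mse_confidence_interval([5.0] * 10)
        assert lo == hi == pytest.approx(5.0)

    def test_two_folds_symmetric(self):
        lo, hi = mse_confidence_interval([0.0, 2.0])
        assert lo + hi == pytest.approx(2.0)

    def test_matches_t_formula(self, rng):
        vals = rng.random(10) * 100
        lo, hi = mse_confidence_interval(vals)
        half = scipy.stats.t.ppf(0.975, 9) * vals.std(ddof=1) / np.sqrt(10)
        assert abs(lo - (vals.mean() - half)) < 1e-10
        assert abs(hi - (vals.mean() + half)) < 1e-10

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            mse_confidence_interval([1.0])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([-1.0, 0.0, 31.0, 40.0])
        m = classification_metrics(labels, scores, threshold=30.0)
        assert m.auc == 1.0 and m.aupr == 1.0
        assert m.acc == 1.0 and m.f1 == 1.0 and m.kappa == 1.0

    def test_chance_level_kappa_near_zero(self, rng):
        labels = rng.integers(0, 2, size=4000)
        scores = rng.normal(30.0, 10.0, size=4000)  # independent of labels
        m = classification_metrics(labels, scores, threshold=30.0)
        assert abs(m.kappa) < 0.05

    def test_matches_brute_force_oracles(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]  # both classes present
        scores = np.round(rng.normal(0, 2, size=30), 1)  # induce ties
        m = classification_metrics(labels, scores, threshold=0.5)
        assert abs(m.auc - auc_all_pairs(labels, scores)) < 1e-10
        assert abs(m.aupr - aupr_step(labels, scores)) < 1e-10
        preds = (scores >= 0.5).astype(int)
        assert abs(m.acc - np.mean(preds == labels)) < 1e-10
        tp = np.sum((preds == 1) & (labels == 1))
        fp = np.sum((preds == 1) & (labels == 0))
        fn = np.sum((preds == 0) & (labels == 1))
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert abs(m.f1 - f1) < 1e-10
        assert abs(m.kappa - kappa_confusion(labels, preds)) < 1e-10

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.standard_normal(40)
        m1 = classification_metrics(labels, scores, 0.0)
        m2 = classification_metrics(labels, np.exp(scores), np.exp(0.0))
        assert abs(m1.auc - m2.auc) < 1e-12

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="single class"):
            m = classification_metrics(np.ones(5, dtype=int), np.arange(5.0), 2.0)
        assert not m.rank_defined and np.isnan(m.auc)
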