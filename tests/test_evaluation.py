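"""Evaluation protocol: stratified folds, cross-validation harness,
confusion-matrix metrics (vs a loop oracle) and one-vs-rest ROC."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

import brainstage as bs
from brainstage.evaluate import ConfusionMatrix, METRIC_NAMES


# ------------------------------------------------------------------- oracle


def metrics_oracle(counts, class_order):
    """Exhaustive per-class loop over one-vs-rest reductions."""
    total = counts.sum()
    per_class = {}
    for i, label in enumerate(class_order):
        tp = fp = fn = tn = 0.0
        for a in range(len(class_order)):
            for p in range(len(class_order)):
                n = counts[a, p]
                if a == i and p == i:
                    tp += n
                elif a == i:
                    fn += n
                elif p == i:
                    fp += n
                else:
                    tn += n
        per_class[label] = {
            "accuracy": (tp + tn) / total if total else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }
    return per_class


class OracleClassifier(ClassifierMixin, BaseEstimator):
    """Memorises the full label table and answers perfectly."""

    def __init__(self, lookup=None):
        self.lookup = lookup

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.array([self.lookup[tuple(row)] for row in X])


class MajorityClassifier(ClassifierMixin, BaseEstimator):
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.classes_ = vals
        self.majority_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=object)


# --------------------------------------------------------------------- folds


def test_folds_exact_division():
    labels = np.array(["CN", "AD"] * 5)
    fa = bs.make_folds(labels, 5, seed=0)
    sizes = [len(fa.test_indices(f)) for f in range(5)]
    assert sizes == [2] * 5


def test_folds_deterministic_and_stratified():
    labels = np.repeat(["CN", "MCI", "AD"], 25)
    fa1 = bs.make_folds(labels, 5, seed=9)
    fa2 = bs.make_folds(labels, 5, seed=9)
    np.testing.assert_array_equal(fa1.fold_of, fa2.fold_of)
    for f in range(5):
        te = fa1.test_indices(f)
        _, counts = np.unique(labels[te], return_counts=True)
        assert list(counts) == [5, 5, 5]


def test_folds_reject_tiny_class():
    labels = np.array(["CN"] * 10 + ["AD"] * 3)
    with pytest.raises(ValueError):
        bs.make_folds(labels, 5, seed=0)


# ----------------------------------------------------------------- confusion


def test_confusion_hand_counts():
    cm = bs.confusion(["CN", "CN", "AD"], ["CN", "MCI", "AD"])
    assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[2, 2] == 1
    assert cm.total == 3
    perfect = bs.confusion(["CN", "MCI", "AD"], ["CN", "MCI", "AD"])
    assert np.all(perfect.counts == np.eye(3))


def test_confusion_conservation(rng):
    y_true = rng.choice(list(bs.CLASSES), 100)
    y_pred = rng.choice(list(bs.CLASSES), 100)
    assert bs.confusion(y_true, y_pred).total == 100


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError):
        bs.confusion(["CN"], ["Severe"])


# ------------------------------------------------------------------- metrics


def test_metrics_hand_arithmetic_two_class():
    cm = ConfusionMatrix(np.array([[50, 10], [5, 35]]), class_order=("CN", "AD"))
    rep = bs.metrics_from_confusion(cm)
    assert rep.accuracy == pytest.approx(0.85)
    assert rep.per_class["CN"]["recall"] == pytest.approx(50 / 60)
    assert rep.per_class["CN"]["precision"] == pytest.approx(50 / 55)
    assert rep.per_class["CN"]["specificity"] == pytest.approx(35 / 40)


def test_metrics_perfect_diagonal():
    rep = bs.metrics_from_confusion(ConfusionMatrix(np.diag([7, 8, 9])))
    assert rep.accuracy == 1.0
    assert all(v == 1.0 for v in rep.macro.values())


def test_metrics_match_loop_oracle(rng):
    for _ in range(1000):
        counts = rng.integers(0, 20, size=(3, 3))
        if counts.sum() == 0:
            continue
        cm = ConfusionMatrix(counts)
        rep = bs.metrics_from_confusion(cm)
        expected = metrics_oracle(counts, cm.class_order)
        for c in cm.class_order:
            for m in METRIC_NAMES:
                assert rep.per_class[c][m] == pytest.approx(expected[c][m], abs=1e-12)
        assert rep.accuracy == pytest.approx(np.trace(counts) / counts.sum(), abs=1e-12)


def test_metrics_f1_is_harmonic_mean(rng):
    counts = rng.integers(1, 30, size=(3, 3))
    rep = bs.metrics_from_confusion(ConfusionMatrix(counts))
    for c in rep.per_class.values():
        p, r = c["precision"], c["recall"]
        if p + r > 0:
            assert c["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


def test_metrics_zero_denominator_flagged():
    # nothing predicted as AD -> AD precision denominator is zero
    counts = np.array([[5, 0, 0], [0, 5, 0], [3, 2, 0]])
    rep = bs.metrics_from_confusion(ConfusionMatrix(counts))
    assert rep.per_class["AD"]["precision"] == 0.0
    assert "AD.precision" in rep.zero_denominator_flags
    assert not np.isnan(list(rep.macro.values())).any()


# ----------------------------------------------------------------------- ROC


def test_roc_one_hot_truth_perfect():
    y = np.array(["CN", "MCI", "AD", "CN", "MCI", "AD"])
    scores = np.stack([(y == c).astype(float) for c in bs.CLASSES], axis=1)
    curves = bs.roc_one_vs_rest(y, scores)
    for c in curves:
        assert c.auc == pytest.approx(1.0)


def test_roc_random_scores_near_half(rng):
    y = rng.choice(list(bs.CLASSES), 600)
    scores = rng.random((600, 3))
    curves = bs.roc_one_vs_rest(y, scores)
    for c in curves:
        assert abs(c.auc - 0.5) <= 0.1


def test_roc_sign_reversal_antisymmetry(rng):
    y = rng.choice(list(bs.CLASSES), 200)
    scores = rng.random((200, 3))
    fwd = bs.roc_one_vs_rest(y, scores)
    rev = bs.roc_one_vs_rest(y, -scores)
    for a, b in zip(fwd, rev):
        assert b.auc == pytest.approx(1.0 - a.auc, abs=1e-9)


def test_roc_flags_absent_class():
    y = np.array(["CN"] * 10)
    with pytest.warns(UserWarning):
        curves = bs.roc_one_vs_rest(y, np.random.default_rng(0).random((10, 3)))
    assert not curves[2].defined  # AD never occurs


# ----------------------------------------------------------- cross-validation


def _labelled_data(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n_per_class * 3, 4))
    y = np.repeat(list(bs.CLASSES), n_per_class)
    return X, y


def test_cv_oracle_classifier_perfect_every_fold():
    X, y = _labelled_data()
    lookup = {tuple(row): lab for row, lab in zip(X, y)}
    rep = bs.cross_validate(X, y, lambda: OracleClassifier(lookup))
    assert all(m.accuracy == 1.0 for m in rep.fold_metrics)
    assert rep.mean_metrics["accuracy"] == 1.0


def test_cv_majority_dummy_near_chance():
    X, y = _labelled_data(20)
    rep = bs.cross_validate(X, y, MajorityClassifier)
    assert abs(rep.pooled.accuracy - 1 / 3) <= 0.05


def test_cv_partition_property():
    X, y = _labelled_data(7)
    folds = bs.make_folds(y, 5, seed=1)
    test_sets = [set(folds.test_indices(f)) for f in range(5)]
    assert set().union(*test_sets) == set(range(len(y)))
    for i in range(5):
        for j in range(i + 1, 5):
            assert not (test_sets[i] & test_sets[j])


def test_cv_pooled_accuracy_is_count_weighted():
    X, y = _labelled_data(9)  # 27 samples: folds of unequal size
    rep = bs.cross_validate(X, y, MajorityClassifier)
    pooled_counts = np.sum([c.counts for c in rep.fold_confusions], axis=0)
    assert rep.pooled.accuracy == pytest.approx(
        np.trace(pooled_counts) / pooled_counts.sum(), abs=1e-12
    )


def test_cv_augmenter_cannot_touch_test_folds():
    X, y = _labelled_data(10)

    def bad_augmenter(tr_idx):
        # claims a sample from outside the training fold
        all_idx = np.arange(len(y))
        outside = np.setdiff1d(all_idx, tr_idx)[:1]
        return X[outside], y[outside], outside

    with pytest.raises(AssertionError, match="outside the training fold"):
        bs.cross_validate(X, y, MajorityClassifier, augmenter=bad_augmenter)

    def good_augmenter(tr_idx):
        take = tr_idx[:3]
        return X[take] + 0.01, y[take], take

    rep = bs.cross_validate(X, y, MajorityClassifier, augmenter=good_augmenter)
    assert sum(c.total for c in rep.fold_confusions) == len(y)  # tests unchanged


def test_cv_annotates_fold_of_training_failure():
    X, y = _labelled_data(10)

    class Exploder(BaseEstimator):
        def fit(self, X, y):
            raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="fold 0"):
        bs.cross_validate(X, y, Exploder)
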