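"""Unit tests for splitting, informedness, AUROC, tuning, and OvA training."""

import warnings

import numpy as np
import pytest

from oracles import pairwise_auroc
from petsurv.classify import (
    auroc,
    baseline_knn,
    evaluate_holdout,
    informedness,
    split_train_test,
    train_ova,
    tune_hyperparameters,
)
from petsurv.laplacian import ClassFeatureRanking


def _make_ranking(class_id, n_features, m):
    scores = np.arange(n_features, dtype=float)
    return ClassFeatureRanking(
        class_id=class_id,
        scores=scores,
        order=np.arange(n_features),
        m=m,
        undefined=np.zeros(n_features, dtype=bool),
    )


def _blobs(n_per_class=30, seed=0):
    """Three linearly separable blobs in 6 dimensions."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, centre in enumerate([0.0, 4.0, 8.0], start=1):
        X.append(rng.normal(centre, 0.4, size=(n_per_class, 6)))
        y += [c] * n_per_class
    return np.vstack(X), np.array(y)


class TestSplit:
    def test_cohort_scale_test_size(self):
        ids = [f"s{i}" for i in range(418)]
        labels = np.repeat([1, 2, 3], [255, 124, 39])
        train, test = split_train_test(ids, labels, test_fraction=0.1, seed=0)
        assert len(test) == 42
        assert len(train) + len(test) == 418
        assert set(train).isdisjoint(test)

    def test_small_balanced_cohort_one_test_subject_per_class(self):
        ids = list(range(10))
        labels = np.array([1] * 5 + [2] * 5)
        _, test = split_train_test(ids, labels, test_fraction=0.1, seed=1)
        assert len(test) == 2
        assert {1, 2} == {labels[i] for i in test}

    def test_same_seed_identical_split(self):
        ids = list(range(50))
        labels = np.tile([1, 2], 25)
        assert split_train_test(ids, labels, seed=5) == split_train_test(ids, labels, seed=5)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            split_train_test([1, 2, 3], np.array([1, 1, 2]))


class TestInformedness:
    def test_perfect_classifier(self):
        assert informedness((10, 0, 0, 20)) == pytest.approx(1.0)

    def test_constant_positive_prediction_is_uninformed(self):
        assert informedness((10, 0, 20, 0)) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert informedness((8, 2, 6, 25)) == pytest.approx(0.8 + 25 / 31 - 1)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            informedness((0, 0, 3, 4))

    @pytest.mark.parametrize("confusion", [(8, 2, 6, 25), (3, 7, 1, 9), (5, 5, 5, 5)])
    def test_equals_twice_balanced_accuracy_minus_one(self, confusion):
        tp, fn, fp, tn = confusion
        bal_acc = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
        assert informedness(confusion) == pytest.approx(2 * bal_acc - 1)


class TestAuroc:
    def test_perfect_and_anticorrelated_orientation(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auroc(y, np.array([0.9, 0.8, 0.2, 0.1])) < 0.5

    def test_matches_pairwise_probability_oracle_with_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # force ties
            assert auroc(y, scores) == pytest.approx(
                pairwise_auroc(y, scores), abs=1e-12
            )


class TestTuning:
    def test_budget_one_returns_single_configuration(self):
        X, y = _blobs(12, seed=1)
        res = tune_hyperparameters(X[:48], (y[:48] == 1).astype(int), budget=1, folds=3, seed=0)
        assert len(res.trajectory) == 1

    def test_separable_data_reaches_perfect_cv_informedness(self):
        X, y = _blobs(20, seed=2)
        res = tune_hyperparameters(X, (y == 1).astype(int), budget=25, folds=10, seed=0)
        assert res.cv_informedness == pytest.approx(1.0)

    def test_fixed_seed_gives_identical_trajectory(self):
        X, y = _blobs(10, seed=3)
        a = tune_hyperparameters(X, (y == 2).astype(int), budget=12, folds=3, seed=4)
        b = tune_hyperparameters(X, (y == 2).astype(int), budget=12, folds=3, seed=4)
        assert a.trajectory == b.trajectory

    def test_single_class_labels_rejected(self):
        X, _ = _blobs(5)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, np.ones(len(X), dtype=int), budget=2)


class TestOvaTraining:
    def test_three_classes_three_models_with_own_feature_sets(self):
        X, y = _blobs(15, seed=4)
        rankings = {c: _make_ranking(c, 6, m=c + 2) for c in (1, 2, 3)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_ova(X, y, rankings, budget=4, folds=3, seed=0, method="random")
        assert [m.class_id for m in models] == [1, 2, 3]
        assert [m.feature_set.size for m in models] == [3, 4, 5]

    def test_overlapping_feature_sets_allowed(self):
        X, y = _blobs(12, seed=5)
        rankings = {c: _make_ranking(c, 6, m=6) for c in (1, 2, 3)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_ova(X, y, rankings, budget=2, folds=3, seed=0, method="random")
        report = evaluate_holdout(models, X, y)
        assert set(report.per_class) == {1, 2, 3}

    def test_missing_ranking_rejected(self):
        X, y = _blobs(10, seed=6)
        with pytest.raises(ValueError, match="missing"):
            train_ova(X, y, {1: _make_ranking(1, 6, 3)}, budget=1, folds=3)


class TestEvaluate:
    def test_test_class_absent_flagged_undefined(self):
        X, y = _blobs(12, seed=7)
        rankings = {c: _make_ranking(c, 6, m=6) for c in (1, 2, 3)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_ova(X, y, rankings, budget=2, folds=3, seed=0, method="random")
        X_test, y_test = X[y != 3], y[y != 3]
        report = evaluate_holdout(models, X_test, y_test)
        assert not report.per_class[3]["defined"]
        assert report.per_class[1]["defined"]

    def test_error_rate_arithmetic_on_41_subject_holdout(self):
        # 2 mistakes out of 41 one-vs-all decisions
        assert (2 / 41) * 100 == pytest.approx(4.878, abs=1e-3)


class TestKnnBaseline:
    def test_one_neighbor_perfect_on_training_points(self):
        X, y = _blobs(10, seed=8)
        rankings = {c: _make_ranking(c, 6, m=6) for c in (1, 2, 3)}
        report = baseline_knn(X, y, rankings, X, y, k_neighbors=1)
        for row in report.per_class.values():
            assert row["error_rate"] == 0.0

    def test_empty_feature_set_rejected(self):
        X, y = _blobs(8, seed=9)
        rankings = {c: _make_ranking(c, 6, m=0) for c in (1, 2, 3)}
        with pytest.raises(ValueError, match="empty"):
            baseline_knn(X, y, rankings, X, y)

    def test_too_many_neighbors_rejected(self):
        X, y = _blobs(4, seed=10)
        rankings = {c: _make_ranking(c, 6, m=6) for c in (1, 2, 3)}
        with pytest.raises(ValueError, match="k_neighbors"):
            baseline_knn(X, y, rankings, X, y, k_neighbors=len(X))

    def test_knn_rarely_beats_tuned_svm_on_phantom(self, default_phantom, phantom_rankings):
        """The margin classifier should match or beat K-NN on most splits."""
        ph = default_phantom
        wins = 0
        n_seeds = 10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_seeds):
                idx = np.arange(ph.fm.n_subjects)
                tr, te = split_train_test(idx, ph.labels, seed=s)
                tr, te = np.asarray(tr), np.asarray(te)
                svm = train_ova(
                    ph.fm.values[tr], ph.labels[tr], phantom_rankings,
                    budget=10, folds=5, seed=s, method="random",
                )
                svm_rep = evaluate_holdout(svm, ph.fm.values[te], ph.labels[te])
                knn_rep = baseline_knn(
                    ph.fm.values[tr], ph.labels[tr], phantom_rankings,
                    ph.fm.values[te], ph.labels[te],
                )
                j_svm = np.nanmean([r["informedness"] for r in svm_rep.per_class.values()])
                j_knn = np.nanmean([r["informedness"] for r in knn_rep.per_class.values()])
                wins += j_knn <= j_svm + 1e-12
        assert wins >= 0.6 * n_seeds
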