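"""Yield discretization, weighted knn prediction, tuning and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.neighbors import KNeighborsClassifier

import nutribalance as nb
from nutribalance.diagnosis import HIGH, LOW


def two_clusters(rng, n_per_class=100, dim=7, separation=4.0):
    """Two spherical Gaussian classes separated along the first axis."""
    shift = np.zeros(dim)
    shift[0] = separation  # in units of the (unit) pooled SD
    x_high = rng.standard_normal((n_per_class, dim))
    x_low = rng.standard_normal((n_per_class, dim)) + shift
    X = np.vstack([x_high, x_low])
    y = np.array([HIGH] * n_per_class + [LOW] * n_per_class)
    return X, y


class TestDiscretize:
    def test_basic_split_and_tie_rule(self):
        classes = nb.discretize_yield([50.0, 70.0, 60.0], cutoff=60.0)
        assert list(classes) == [LOW, HIGH, HIGH]  # ties go to high

    def test_all_low(self):
        assert set(nb.discretize_yield([1.0, 2.0], cutoff=60.0)) == {LOW}

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            nb.discretize_yield([-1.0], cutoff=60.0)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            nb.discretize_yield([1.0], cutoff=0.0)


class TestKnnPredict:
    def test_single_training_specimen(self):
        pred = nb.knn_predict([[0.0, 0.0]], [LOW], [[5.0, 5.0], [-1.0, 0.0]],
                              nb.KnnConfig(k=1))
        assert list(pred) == [LOW, LOW]

    def test_k1_self_prediction_is_perfect(self, rng):
        X, y = two_clusters(rng, n_per_class=30, separation=0.0)
        pred = nb.knn_predict(X, y, X, nb.KnnConfig(k=1, seed=0))
        assert (pred == y).all()

    @pytest.mark.parametrize("kernel", ["rectangular", "triangular", "optimal"])
    def test_separated_clusters_high_accuracy(self, rng, kernel):
        X, y = two_clusters(rng, n_per_class=100, separation=4.0)
        Xq, yq = two_clusters(rng, n_per_class=100, separation=4.0)
        pred = nb.knn_predict(X, y, Xq, nb.KnnConfig(k=10, kernel=kernel,
                                                     seed=0))
        assert (pred == yq).mean() >= 0.95

    def test_rectangular_matches_sklearn_majority_vote(self, rng):
        # independent oracle on the same draw; odd k avoids vote ties
        X, y = two_clusters(rng, n_per_class=50, separation=2.0)
        Xq, _ = two_clusters(rng, n_per_class=25, separation=2.0)
        ours = nb.knn_predict(X, y, Xq, nb.KnnConfig(
            k=5, minkowski_p=2.0, kernel="rectangular", seed=0))
        oracle = KNeighborsClassifier(n_neighbors=5, weights="uniform",
                                      p=2).fit(X, y).predict(Xq)
        assert (ours == oracle).all()

    def test_invariant_to_coordinate_permutation(self, rng):
        X, y = two_clusters(rng, n_per_class=40, separation=1.5)
        Xq, _ = two_clusters(rng, n_per_class=20, separation=1.5)
        cfg = nb.KnnConfig(k=7, minkowski_p=4.0, kernel="optimal", seed=3)
        perm = rng.permutation(X.shape[1])
        assert (nb.knn_predict(X, y, Xq, cfg)
                == nb.knn_predict(X[:, perm], y, Xq[:, perm], cfg)).all()

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            nb.knn_predict([[0.0], [1.0]], [HIGH, LOW], [[0.5]],
                           nb.KnnConfig(k=5))


class TestTuneKnn:
    def test_grid_of_one_returns_it(self, rng):
        X, y = two_clusters(rng, n_per_class=30)
        best, _ = nb.tune_knn(X, y, grid={"k": [3], "minkowski_p": [2.0],
                                          "kernel": ["rectangular"]},
                              folds=5, seed=1)
        assert (best.k, best.minkowski_p, best.kernel) == (3, 2.0, "rectangular")

    def test_separable_data_perfect_cv_with_k1(self, rng):
        X, y = two_clusters(rng, n_per_class=30, separation=50.0)
        best, accuracy = nb.tune_knn(X, y, grid={"k": [1]}, folds=5, seed=1)
        assert accuracy == 1.0 and best.k == 1

    def test_deterministic_given_seed(self, rng):
        X, y = two_clusters(rng, n_per_class=40, separation=1.0)
        grid = {"k": [3, 7], "minkowski_p": [2.0, 4.0]}
        first = nb.tune_knn(X, y, grid=grid, folds=5, seed=11)
        second = nb.tune_knn(X, y, grid=grid, folds=5, seed=11)
        assert first == second

    def test_class_missing_from_training_split_rejected(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([HIGH] * 5 + [LOW])
        with pytest.raises(ValueError, match="absent"):
            nb.tune_knn(X, y, grid={"k": [1]}, folds=6, seed=0)


class TestConfusionPartition:
    def test_all_correct_half_high(self):
        t = np.array([HIGH, HIGH, LOW, LOW])
        cp = nb.partition_confusion(t, t)
        assert (cp.tn, cp.tp, cp.fn, cp.fp) == (2, 2, 0, 0)

    def test_inverted_predictions(self):
        t = np.array([HIGH, HIGH, LOW, LOW])
        p = np.array([LOW, LOW, HIGH, HIGH])
        cp = nb.partition_confusion(t, p)
        assert (cp.tn, cp.tp) == (0, 0) and (cp.fn, cp.fp) == (2, 2)

    def test_four_specimen_hand_case(self):
        cp = nb.partition_confusion([HIGH, HIGH, LOW, LOW],
                                    [HIGH, LOW, HIGH, LOW])
        assert (cp.tn, cp.fp, cp.fn, cp.tp) == (1, 1, 1, 1)
        assert cp.category_of() == {0: "TN", 1: "FP", 2: "FN", 3: "TP"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nb.partition_confusion([HIGH], [HIGH, LOW])

    def test_counts_sum_to_total(self, rng):
        t = rng.choice([HIGH, LOW], size=40)
        p = rng.choice([HIGH, LOW], size=40)
        cp = nb.partition_confusion(t, p)
        assert cp.total == 40
        assert len(cp.category_of()) == 40


class TestDiagnosticMetrics:
    def test_study_scale_counts(self):
        cp = nb.ConfusionPartition.from_counts(tn=96, fn=4, tp=85, fp=10)
        m = nb.diagnostic_metrics(cp)
        assert m["accuracy"] == pytest.approx(181 / 195)
        assert round(m["accuracy"], 2) == 0.93
        assert round(m["npv"], 2) == 0.96
        assert round(m["ppv"], 2) == 0.89
        assert round(m["sensitivity"], 2) == 0.96
        assert round(m["specificity"], 2) == 0.91

    def test_degenerate_partitions(self):
        perfect = nb.diagnostic_metrics(
            nb.ConfusionPartition.from_counts(10, 0, 10, 0))
        assert set(perfect.values()) == {1.0}
        inverted = nb.diagnostic_metrics(
            nb.ConfusionPartition.from_counts(0, 5, 0, 5))
        assert inverted["accuracy"] == 0.0

    def test_undefined_ratios_are_nan_not_zero(self):
        m = nb.diagnostic_metrics(nb.ConfusionPartition.from_counts(5, 0, 0, 0))
        assert np.isnan(m["ppv"]) and np.isnan(m["sensitivity"])
        assert m["npv"] == 1.0

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            nb.diagnostic_metrics(nb.ConfusionPartition.from_counts(0, 0, 0, 0))

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_metric_identities(self, counts):
        tn, fn, tp, fp = counts
        if tn + fn + tp + fp == 0:
            return
        m = nb.diagnostic_metrics(
            nb.ConfusionPartition.from_counts(tn, fn, tp, fp))
        assert m["accuracy"] == pytest.approx((tn + tp) / (tn + fn + tp + fp))
        for value in m.values():
            assert np.isnan(value) or 0.0 <= value <= 1.0
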