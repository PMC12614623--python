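"""k-NN prediction, distance metrics, k selection and the baselines."""

import math

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from hybridbci import (
    KNNClassifier,
    ValidationError,
    baseline_classify,
    euclidean_distance,
    knn_predict,
    select_k,
)
from hybridbci.knn import METRICS, _stratified_indices


# ---------------------------------------------------------------------------
# independent brute-force oracle (loops + the stated tie-break rule)

def _dist(metric, a, b):
    if metric == "euclidean":
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
    if metric == "cityblock":
        return sum(abs(x - y) for x, y in zip(a, b))
    if metric == "cosine":
        na = math.sqrt(sum(x * x for x in a))
        nb = math.sqrt(sum(y * y for y in b))
        return 1.0 - sum(x * y for x, y in zip(a, b)) / (na * nb)
    if metric == "correlation":
        ma = sum(a) / len(a)
        mb = sum(b) / len(b)
        da = [x - ma for x in a]
        db = [y - mb for y in b]
        na = math.sqrt(sum(x * x for x in da))
        nb = math.sqrt(sum(y * y for y in db))
        return 1.0 - sum(x * y for x, y in zip(da, db)) / (na * nb)
    raise AssertionError(metric)


def _brute_knn(train_X, train_y, test_X, k, metric):
    preds = []
    for row in test_X:
        d = [(_dist(metric, row, t), i) for i, t in enumerate(train_X)]
        d.sort()
        neigh = [train_y[i] for _, i in d[:k]]
        best = max(set(neigh), key=neigh.count)
        tied = {c for c in set(neigh) if neigh.count(c) == neigh.count(best)}
        if len(tied) > 1:
            best = next(lab for lab in neigh if lab in tied)
        preds.append(best)
    return np.array(preds)


class TestEuclidean:
    def test_three_four_five_triangle(self):
        assert euclidean_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_identical_vectors_are_zero(self):
        assert euclidean_distance((1.5, -2.0, 3.0), (1.5, -2.0, 3.0)) == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            g, h = rng.standard_normal((2, 10))
            expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(g, h)))
            assert euclidean_distance(g, h) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            euclidean_distance((1, 2), (1, 2, 3))


class TestKnnPredict:
    def test_exact_train_row_with_k1(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.arange(1, 5).repeat(3)[:10]
        pred = knn_predict(X, y, X[[3]], k=1)
        assert pred[0] == y[3]

    def test_single_label_train_is_constant(self, rng):
        X = rng.standard_normal((8, 3))
        y = np.full(8, 2)
        for k in (1, 3, 7):
            assert np.all(knn_predict(X, y, rng.standard_normal((5, 3)), k=k) == 2)

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_brute_force_oracle(self, metric, k):
        rng = np.random.default_rng(100 * METRICS.index(metric) + k)
        for _ in range(5):
            n_train = rng.integers(k + 1, 50)
            X = rng.standard_normal((n_train, 4))
            y = rng.integers(1, 5, size=n_train)
            T = rng.standard_normal((8, 4))
            np.testing.assert_array_equal(
                knn_predict(X, y, T, k=k, distance=metric),
                _brute_knn(X, y, T, k, metric),
            )

    def test_empty_train_or_bad_metric_raises(self, rng):
        with pytest.raises(ValidationError):
            KNNClassifier().fit(np.empty((0, 3)), np.empty(0))
        with pytest.raises(ValidationError):
            KNNClassifier(metric="hamming").fit(rng.standard_normal((5, 2)),
                                                np.ones(5))


class TestSelectK:
    def test_single_candidate_is_forced(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.tile([1, 2, 3, 4], 10)
        assert select_k(X, y, candidate_ks=[5], seed=0) == 5

    def test_separable_blobs_reach_perfect_inner_accuracy(self):
        X, y = make_blobs(n_samples=80, centers=4, cluster_std=0.05,
                          random_state=0)
        y = y + 1
        k = select_k(X, y, seed=0)
        # chosen k must classify a held-out stratified split perfectly
        rng = np.random.default_rng(99)
        tr, va = _stratified_indices(y, 0.8, rng)
        assert np.all(knn_predict(X[tr], y[tr], X[va], k=k) == y[va])

    def test_matches_replay_oracle(self, rng):
        """Re-derive the same inner splits and re-score every candidate with
        the brute-force k-NN; the selections must agree."""
        X = rng.standard_normal((48, 3))
        y = np.tile([1, 2, 3, 4], 12)
        candidates, n_sub, seed = (1, 3, 5), 6, 17
        picked = select_k(X, y, candidate_ks=candidates, n_subsamples=n_sub,
                          seed=seed)
        replay_rng = np.random.default_rng(seed)
        scores = np.zeros((n_sub, len(candidates)))
        for s in range(n_sub):
            tr, va = _stratified_indices(y, 0.8, replay_rng)
            for j, k in enumerate(candidates):
                pred = _brute_knn(X[tr], y[tr], X[va], k, "euclidean")
                scores[s, j] = np.mean(pred == y[va])
        expected = candidates[int(np.argmax(scores.mean(axis=0)))]
        assert picked == expected

    def test_candidate_exceeding_rows_raises(self, rng):
        X = rng.standard_normal((8, 2))
        y = np.tile([1, 2, 3, 4], 2)
        with pytest.raises(ValidationError):
            select_k(X, y, candidate_ks=[9], seed=0)


class TestBaselines:
    @pytest.mark.parametrize("alg", ["svm", "dt", "rf"])
    def test_separable_blobs_are_learned(self, alg):
        X, y = make_blobs(n_samples=120, centers=4, cluster_std=0.05,
                          random_state=1)
        y = y + 1
        pred = baseline_classify(X[:90], y[:90], X[90:], alg, seed=0)
        assert np.mean(pred == y[90:]) >= 0.95

    @pytest.mark.parametrize("alg", ["svm", "dt", "rf"])
    def test_single_class_train_predicts_constant(self, alg, rng):
        X = rng.standard_normal((10, 3))
        pred = baseline_classify(X, np.full(10, 3), rng.standard_normal((4, 3)),
                                 alg, seed=0)
        assert np.all(pred == 3)

    def test_fixed_seed_is_deterministic(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.integers(1, 5, 60)
        T = rng.standard_normal((20, 5))
        a = baseline_classify(X, y, T, "rf", seed=5)
        b = baseline_classify(X, y, T, "rf", seed=5)
        np.testing.assert_array_equal(a, b)

    def test_unknown_algorithm_raises(self, rng):
        with pytest.raises(ValidationError):
            baseline_classify(np.ones((4, 2)), [1, 1, 2, 2], np.ones((1, 2)),
                              "mlp")
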