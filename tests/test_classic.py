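"""KNN, entropy forest and linear SVM against oracles and closed forms."""

import numpy as np
import pytest

from pointfall.classic import (
    LabeledPointSet,
    LinearSeparator,
    entropy,
    forest_classify,
    forest_train,
    knn_classify,
    knn_classify_batch,
    svm_classify,
    svm_train,
)
from pointfall.core import ParameterError


def brute_force_knn(train, query, k):
    """Independent exhaustive-search oracle with the same tie conventions."""
    d = np.sqrt(((train.vectors - query) ** 2).sum(axis=1))
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    votes = {}
    for i in order:
        votes[train.labels[i]] = votes.get(train.labels[i], 0) + 1
    best = max(votes.values())
    return min(c for c, v in votes.items() if v == best)


class TestKNN:
    def test_query_equal_training_point(self, rng):
        train = LabeledPointSet(rng.normal(0, 1, (20, 3)), rng.integers(1, 4, 20))
        assert knn_classify(train, train.vectors[7], k=1) == train.labels[7]

    def test_euclidean_distance_ranking(self):
        # d((0,0,0),(1,2,2)) = 3: the (1,2,2) point must outrank one at distance 3.5
        train = LabeledPointSet([[1, 2, 2], [3.5, 0, 0]], [2, 3])
        assert knn_classify(train, [0.0, 0.0, 0.0], k=1) == 2

    def test_matches_exhaustive_oracle(self, rng):
        train = LabeledPointSet(rng.normal(0, 1, (200, 3)), rng.integers(1, 4, 200))
        queries = rng.normal(0, 1, (50, 3))
        for k in (1, 3, 5):
            ours = knn_classify_batch(train, queries, k)
            oracle = [brute_force_knn(train, q, k) for q in queries]
            assert np.array_equal(ours, oracle)

    def test_dimension_mismatch_rejected(self, rng):
        train = LabeledPointSet(rng.normal(0, 1, (10, 3)), rng.integers(1, 4, 10))
        with pytest.raises(ParameterError):
            knn_classify(train, [0.0, 0.0], k=1)

    def test_k_out_of_range(self, rng):
        train = LabeledPointSet(rng.normal(0, 1, (5, 3)), rng.integers(1, 4, 5))
        with pytest.raises(ParameterError):
            knn_classify(train, [0, 0, 0], k=6)


class TestEntropy:
    def test_pure_node_zero(self):
        assert entropy([1.0, 0.0]) == 0.0

    def test_even_split_one_bit(self):
        assert entropy([0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_three_quarter(self):
        # closed form: 2 - 0.75*log2(3)
        assert entropy([0.25, 0.75]) == pytest.approx(2 - 0.75 * np.log2(3), abs=1e-12)
        assert entropy([0.25, 0.75]) == pytest.approx(0.8113, abs=1e-4)


def _blobs(rng, n_per=60, d=3, spread=4.0):
    X = np.concatenate([
        rng.normal(0, 1, (n_per, d)),
        rng.normal(spread, 1, (n_per, d)),
        rng.normal(-spread, 1, (n_per, d)),
    ])
    y = np.repeat([1, 2, 3], n_per)
    return LabeledPointSet(X, y)


class TestForest:
    def test_separable_blobs_classified(self, rng):
        train = _blobs(rng)
        forest = forest_train(train, n_trees=15, seed=0)
        preds = forest_classify(forest, train.vectors)
        assert (preds == train.labels).mean() >= 0.98

    def test_ensemble_at_least_single_tree(self, rng):
        X = rng.normal(0, 1, (200, 3))
        y = (X[:, 0] + 0.5 * rng.normal(0, 1, 200) > 0).astype(int) + 1
        train = LabeledPointSet(X, y)
        single = forest_train(train, n_trees=1, seed=5, max_depth=3)
        many = forest_train(train, n_trees=25, seed=5, max_depth=3)
        acc1 = (forest_classify(single, X) == y).mean()
        accN = (forest_classify(many, X) == y).mean()
        assert accN >= acc1

    def test_single_class_warns_constant(self, rng):
        train = LabeledPointSet(rng.normal(0, 1, (20, 3)), np.full(20, 2))
        with pytest.warns(UserWarning, match="single-class"):
            forest = forest_train(train, n_trees=3, seed=1)
        assert np.all(forest_classify(forest, rng.normal(0, 1, (5, 3))) == 2)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        train = _blobs(rng, n_per=80)
        test = _blobs(np.random.default_rng(99), n_per=40)
        ours = forest_train(train, n_trees=30, seed=2)
        ref = RandomForestClassifier(
            n_estimators=30, criterion="entropy", max_depth=8, random_state=2
        ).fit(train.vectors, train.labels)
        acc_ours = (forest_classify(ours, test.vectors) == test.labels).mean()
        acc_ref = ref.score(test.vectors, test.labels)
        assert abs(acc_ours - acc_ref) <= 0.05


class TestSVM:
    def test_separable_blobs_margins_hold(self, rng):
        X = np.concatenate([rng.normal(3, 0.5, (50, 3)), rng.normal(-3, 0.5, (50, 3))])
        y = np.repeat([1, 3], 50)
        train = LabeledPointSet(X, y)
        sep = svm_train(train, classes=(1, 3))
        preds = svm_classify(sep, X)
        assert np.array_equal(preds, y)
        signed = np.where(y == 1, 1.0, -1.0)
        margins = signed * sep.decision(X)
        assert margins.min() >= 1.0 - 1e-3  # canonical margin constraints

    def test_boundary_point_takes_positive_class(self):
        sep = LinearSeparator(w=np.array([1.0, 0.0]), b=0.0, classes=(1, 3))
        assert svm_classify(sep, [[0.0, 5.0]])[0] == 1

    def test_label_flip_negates_separator(self, rng):
        X = np.concatenate([rng.normal(2, 0.4, (40, 2)), rng.normal(-2, 0.4, (40, 2))])
        y = np.repeat([1, 3], 40)
        train = LabeledPointSet(X, y)
        a = svm_train(train, classes=(1, 3))
        b = svm_train(train, classes=(3, 1))
        assert np.allclose(a.w, -b.w, atol=1e-6)
        assert a.b == pytest.approx(-b.b, abs=1e-6)

    def test_multiclass_request_rejected(self, rng):
        train = _blobs(rng)
        with pytest.raises(ParameterError, match="two classes"):
            svm_train(train, classes=(1, 1))

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.svm import LinearSVC

        X = np.concatenate([rng.normal(2.5, 0.8, (80, 3)), rng.normal(-2.5, 0.8, (80, 3))])
        y = np.repeat([1, 3], 80)
        sep = svm_train(LabeledPointSet(X, y), classes=(1, 3))
        ref = LinearSVC(C=10.0).fit(X, y)
        agree = (svm_classify(sep, X) == ref.predict(X)).mean()
        assert agree >= 0.98
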