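import itertools

import numpy as np
import pytest

from planknet.classify import (
    DEFAULT_THRESHOLD_GRID,
    TrainedClassifier,
    buffered_cv,
    buffered_training_indices,
    encode_position,
    loo_cv,
    micro_f1,
    micro_roc_auc,
    permutation_importance,
    select_threshold,
    standardize,
    train,
)
from planknet.preprocess import haversine_km
from planknet.synthetic_data import sample_locations

SINGLE_C = [{"C": 1.0, "kernel": "linear"}]


def blobs(rng, n_per_class, centers, sd=0.3):
    X, y = [], []
    for label, center in enumerate(centers, start=1):
        X.append(center + sd * rng.standard_normal((n_per_class, len(center))))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestEncodePosition:
    def test_zero_longitude(self):
        assert encode_position(10.0, 0.0) == pytest.approx((10.0, 0.0, 1.0))

    def test_circular(self):
        east = encode_position(0.0, 180.0)
        west = encode_position(0.0, -180.0)
        assert east == pytest.approx(west, abs=1e-12)
        assert east[2] == pytest.approx(-1.0)

    def test_quarter(self):
        _, s, c = encode_position(0.0, 90.0)
        assert (s, c) == pytest.approx((1.0, 0.0), abs=1e-12)


class TestStandardize:
    def test_unit_population_sd(self):
        X = np.array([[1.0], [2.0], [3.0]])
        out, means, sds = standardize(X, np.arange(3))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_held_out_at_fit_mean_maps_to_zero(self):
        X = np.array([[1.0], [3.0], [2.0]])
        out, _, _ = standardize(X, np.array([0, 1]))  # fit mean = 2
        assert out[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_zeroed_with_warning(self, caplog):
        X = np.ones((4, 2))
        X[:, 1] = [1, 2, 3, 4]
        out, _, sds = standardize(X, np.arange(4))
        np.testing.assert_allclose(out[:, 0], 0.0)
        assert sds[0] == 1.0
        assert any("constant" in r.message for r in caplog.records)


class TestTrain:
    def test_separable_blobs_perfect(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng, 20, [np.array([0, 0]), np.array([5, 5])])
        model = train(X, y, "svm", SINGLE_C, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_grid_setting_selected(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, 10, [np.array([0, 0]), np.array([3, 3])])
        model = train(X, y, "svm", [{"C": 7.0, "kernel": "linear"}], seed=0)
        assert model.best_params == {"C": 7.0, "kernel": "linear"}

    def test_shuffled_labels_near_chance(self):
        # permutation null: pooled LOO accuracy over seeds ~ 1/K
        rng = np.random.default_rng(2)
        hits = total = 0
        for seed in range(20):
            X = rng.standard_normal((50, 4))
            y = np.repeat(np.arange(5), 10)
            rng.shuffle(y)
            res = loo_cv(X, y, "nb", seed=seed)
            hits += int(res.accuracy * len(y))
            total += len(y)
        p = hits / total
        sd = np.sqrt(0.2 * 0.8 / total)
        assert abs(p - 0.2) < 3 * sd

    def test_small_class_errors(self):
        X = np.zeros((3, 2))
        y = np.array([1, 1, 2])
        with pytest.raises(ValueError, match="2"):
            train(X, y, "svm", SINGLE_C)

    @pytest.mark.parametrize("algorithm", ["svm", "knn", "nb"])
    def test_algorithms_available(self, algorithm):
        rng = np.random.default_rng(3)
        X, y = blobs(rng, 15, [np.array([0, 0]), np.array([4, 4])])
        model = train(X, y, algorithm, seed=0)
        prob = model.predict_proba(X)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        X, y = blobs(rng, 15, [np.array([0, 0]), np.array([4, 4])])
        model = train(X, y, "svm", SINGLE_C, seed=0, feature_names=["a", "b"])
        model.probability_threshold = 0.28
        model.save(tmp_path / "m")
        back = TrainedClassifier.load(tmp_path / "m")
        np.testing.assert_allclose(back.predict_proba(X), model.predict_proba(X))
        assert back.probability_threshold == 0.28
        assert (tmp_path / "m" / "manifest.json").exists()


class TestLooCv:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        X, y = blobs(rng, 15, [np.array([0, 0]), np.array([8, 8]), np.array([-8, 8])], sd=0.2)
        res = loo_cv(X, y, "svm", SINGLE_C, seed=0)
        assert res.accuracy == 1.0
        assert res.micro_auc == pytest.approx(1.0, abs=1e-9)

    def test_n_predictions_returned(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, 8, [np.array([0, 0]), np.array([2, 2])])
        res = loo_cv(X, y, "knn", [{"n_neighbors": 3}], seed=0)
        assert len(res.y_pred) == len(y)
        assert res.confusion.sum() == len(y)
        assert res.accuracy == pytest.approx(np.trace(res.confusion) / len(y))

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((2, 2)), np.array([1, 2]), "nb")


class TestBufferedCv:
    def test_exclusion_matches_haversine_oracle(self):
        rng = np.random.default_rng(0)
        coords = np.column_stack(
            [rng.uniform(-80, 80, 50), rng.uniform(-180, 180, 50)]
        )
        for i in range(50):
            got = set(buffered_training_indices(coords, i, 2000.0))
            expected = {
                j for j in range(50)
                if j != i and haversine_km(coords[i], coords[j]) >= 2000.0
            }
            assert got == expected

    def test_worked_example(self):
        coords = np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 30.0]])
        idx = buffered_training_indices(coords, 0, 2000.0)
        assert list(idx) == [2]  # ~1113 km excluded, ~3336 km retained

    def test_radius_zero_equals_loo(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, 10, [np.array([0, 0]), np.array([3, 3])])
        coords = np.column_stack([rng.uniform(-10, 10, 20), rng.uniform(-10, 10, 20)])
        loo = loo_cv(X, y, "svm", SINGLE_C, seed=0)
        buf = buffered_cv(X, y, coords, 0.0, "svm", SINGLE_C, seed=0)
        np.testing.assert_allclose(buf.prob, loo.prob)
        assert buf.accuracy == loo.accuracy

    def test_empty_training_set_skipped(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1, 1, 2])
        coords = np.array([[0.0, 0.0], [0.1, 0.1], [0.2, 0.2]])  # all close
        res = buffered_cv(X, y, coords, 5000.0, "nb", seed=0)
        assert len(res.skipped) == 3
        assert len(res.evaluated) == 0

    def test_spatial_leakage_gap(self):
        # labels follow spatial clusters; features are position-only
        rng = np.random.default_rng(0)
        lat, lon, cluster = sample_locations(60, 200.0, 5, rng)
        types = rng.integers(1, 4, cluster.max() + 1)
        y = types[cluster]
        X = np.array([encode_position(la, lo) for la, lo in zip(lat, lon)])
        coords = np.column_stack([lat, lon])
        loo = loo_cv(X, y, "svm", SINGLE_C, seed=0)
        buf = buffered_cv(X, y, coords, 2000.0, "svm", SINGLE_C, seed=0)
        assert loo.micro_auc - buf.micro_auc >= 0.15
        assert buf.accuracy <= loo.accuracy + 0.05


class TestMicroRocAuc:
    def test_perfect(self):
        prob = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert micro_roc_auc(prob, np.array([1, 2, 1]), [1, 2]) == pytest.approx(1.0)

    def test_uniform(self):
        prob = np.full((4, 2), 0.5)
        assert micro_roc_auc(prob, np.array([1, 2, 1, 2]), [1, 2]) == pytest.approx(0.5)

    def test_matches_pairwise_ranking_bruteforce(self):
        prob = np.array([[0.7, 0.3], [0.4, 0.6], [0.55, 0.45]])
        labels = np.array([1, 2, 2])
        classes = np.array([1, 2])
        got = micro_roc_auc(prob, labels, classes)
        # brute force on the pooled one-vs-rest scores
        scores, truths = [], []
        for i, row in enumerate(prob):
            for k, c in enumerate(classes):
                scores.append(row[k])
                truths.append(int(labels[i] == c))
        pos = [s for s, t in zip(scores, truths) if t]
        neg = [s for s, t in zip(scores, truths) if not t]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert got == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            micro_roc_auc(np.array([[1.0, 0.0]]), np.array([1]), [1, 2])


class TestSelectThreshold:
    def test_single_value_grid(self):
        prob = np.array([[0.9, 0.1]])
        assert select_threshold(prob, np.array([1]), np.array([1, 2]), [0.3]) == 0.3

    def test_separated_gap_returns_smallest(self):
        prob = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = np.array([1, 2])
        classes = np.array([1, 2])
        t = select_threshold(prob, labels, classes, [0.2, 0.5, 0.8])
        assert t == 0.2  # every threshold in (0.1, 0.9] is optimal; smallest wins

    def test_matches_bruteforce_sweep(self):
        rng = np.random.default_rng(0)
        prob = rng.dirichlet([2, 2, 2], size=60)
        labels = rng.integers(1, 4, 60)
        classes = np.array([1, 2, 3])
        grid = DEFAULT_THRESHOLD_GRID
        t = select_threshold(prob, labels, classes, grid)
        best = max(grid, key=lambda g: (micro_f1(prob, labels, classes, g), -g))
        assert micro_f1(prob, labels, classes, t) == pytest.approx(
            micro_f1(prob, labels, classes, best)
        )
        assert t <= best


class TestPermutationImportance:
    def _model(self, rng, informative=True):
        n = 80
        y = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 3))
        if informative:
            X[:, 0] += 3 * (y == 2)
        return train(X, y, "svm", SINGLE_C, seed=0, feature_names=["a", "b", "c"]), X, y

    def test_informative_feature_largest(self):
        rng = np.random.default_rng(0)
        model, X, y = self._model(rng)
        imp = permutation_importance(model, X, y, n_repeats=5, seed=1)
        assert imp["a"] > imp["b"] and imp["a"] > imp["c"]

    def test_null_feature_near_zero(self):
        rng = np.random.default_rng(1)
        model, X, y = self._model(rng)
        imp = permutation_importance(model, X, y, n_repeats=20, seed=2)
        assert abs(imp["b"]) < 0.1

    def test_constant_feature_exactly_zero(self):
        # permuting a constant column is the identity: drop must be exactly 0
        rng = np.random.default_rng(2)
        n = 40
        y = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 2))
        X[:, 0] += 3 * (y == 2)
        X[:, 1] = 1.0
        model = train(X, y, "svm", SINGLE_C, seed=0, feature_names=["a", "const"])
        imp = permutation_importance(model, X, y, n_repeats=3, seed=3)
        assert imp["const"] == 0.0
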