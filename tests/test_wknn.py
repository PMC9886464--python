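import numpy as np
import pytest

from pcgkit._core import ValidationError
from pcgkit.wknn import (WKNNModel, cross_validate_k, fit, holdout_split,
                         load_model, predict, predict_batch, save_model)

from ._naive import naive_wknn_predict


def raw_model(X, y, k):
    """Model in raw coordinates (identity standardizer) for geometric tests."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    return WKNNModel(
        train_matrix=X, train_labels=y, k=k,
        feature_mean=np.zeros(X.shape[1]), feature_std=np.ones(X.shape[1]),
        classes=tuple(np.unique(y)),
    )


class TestFit:
    def test_boundary_k_equals_n(self, rng):
        X = rng.standard_normal((5, 3))
        y = ["A", "A", "B", "B", "A"]
        assert fit(X, y, k=5).k == 5
        with pytest.raises(ValidationError):
            fit(X, y, k=6)

    def test_constant_column_standardizes_to_unit_deviation(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0], [4.0, 7.0]])
        model = fit(X, ["A", "A", "B", "B"], k=2)
        assert model.feature_std[1] == 1.0
        np.testing.assert_allclose(model.train_matrix[:, 1], 0.0)

    def test_deterministic(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.repeat(["A", "B"], 10)
        m1, m2 = fit(X, y, k=3), fit(X, y, k=3)
        np.testing.assert_array_equal(m1.train_matrix, m2.train_matrix)


class TestPredict:
    def test_single_training_point(self):
        model = raw_model([[0.0, 0.0], [5.0, 5.0]], ["A", "B"], k=1)
        label, shares = predict(model, np.array([0.1, 0.1]))
        assert label == "A"
        assert shares["A"] == pytest.approx(1.0)

    def test_inverse_distance_vote_flips_plain_majority(self):
        """Two nearby same-class points at d=0.5 outvote three opposing
        points at d=2.0 once votes are weighted 1/d (4.0 vs 1.5), although
        the plain 5-neighbour majority goes the other way."""
        X = np.array([[0.5, 0.0], [-0.5, 0.0],
                      [2.0, 0.0], [0.0, 2.0], [-2.0, 0.0]])
        y = np.array(["green", "green", "red", "red", "red"])
        model = raw_model(X, y, k=5)
        label, shares = predict(model, np.zeros(2))
        assert label == "green"
        assert shares["green"] == pytest.approx(4.0 / 5.5)
        assert shares["red"] == pytest.approx(1.5 / 5.5)
        # unweighted majority among the same 5 neighbours picks red
        values, counts = np.unique(y, return_counts=True)
        assert values[np.argmax(counts)] == "red"

    def test_zero_distance_overrides_other_neighbours(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.01, 1.0], [1.02, 1.0]])
        y = np.array(["A", "A", "B", "B"])
        model = raw_model(X, y, k=4)
        label, shares = predict(model, np.array([1.0, 1.0]))
        assert label == "A"
        assert shares["A"] == 1.0

    def test_dimension_mismatch(self, rng):
        model = fit(rng.standard_normal((10, 3)), np.repeat(["A", "B"], 5), k=2)
        with pytest.raises(ValidationError):
            predict(model, np.ones(4))

    def test_k1_equals_nearest_neighbour(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array(list("ABC") * 10)
        model = fit(X, y, k=1)
        for _ in range(20):
            q = rng.standard_normal(4)
            z = model.standardize(q)
            nn = np.argmin(((model.train_matrix - z) ** 2).sum(axis=1))
            assert predict(model, q)[0] == y[nn]

    def test_scale_invariance_of_predictions(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array(list("AB") * 20)
        queries = rng.standard_normal((10, 5))
        base = predict_batch(fit(X, y, k=7), queries)
        scaled = predict_batch(fit(1000.0 * X, y, k=7), 1000.0 * queries)
        np.testing.assert_array_equal(base, scaled)

    def test_matches_brute_force_oracle(self, rng):
        """200 random instances against an explicit sort-and-sum oracle."""
        for trial in range(200):
            n = int(rng.integers(5, 30))
            d = int(rng.integers(1, 5))
            k = int(rng.integers(1, n + 1))
            X = np.round(rng.standard_normal((n, d)), 2)
            y = rng.choice(["A", "B", "C"], size=n)
            if np.unique(y).size < 2:
                y[0] = "A" if y[1] != "A" else "B"
            q = np.round(rng.standard_normal(d), 2)
            model = raw_model(X, y, k=k)
            expected = naive_wknn_predict(X.tolist(), y.tolist(), q.tolist(),
                                          k, model.classes)
            assert predict(model, q)[0] == expected


class TestHoldoutSplit:
    def test_stratified_proportions(self, rng):
        X = rng.standard_normal((1000, 2))
        y = np.repeat(["AS", "MR", "MS", "MVP", "N"], 200)
        X_tr, y_tr, X_va, y_va = holdout_split(X, y, train_fraction=0.8, seed=0)
        for cls in np.unique(y):
            assert np.sum(y_tr == cls) == 160
            assert np.sum(y_va == cls) == 40

    def test_deterministic_for_seed(self, rng):
        X = rng.standard_normal((50, 2))
        y = np.array(list("AB") * 25)
        a = holdout_split(X, y, seed=3)
        b = holdout_split(X, y, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3], b[3])

    def test_degenerate_fractions_and_classes_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(list("AB") * 5)
        with pytest.raises(ValidationError):
            holdout_split(X, y, train_fraction=1.0)
        with pytest.raises(ValidationError):
            holdout_split(X[:3], np.array(["A", "A", "B"]), train_fraction=0.8)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.standard_normal((12, 4))
        y = np.repeat(["A", "B"], 6)
        model = fit(X, y, k=3, feature_names=("a", "b", "c", "d"),
                    selected_indices=(0, 1, 2, 3), sample_rate=8000.0)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.train_matrix, model.train_matrix)
        assert back.k == 3 and back.classes == model.classes
        assert back.selected_indices == (0, 1, 2, 3)
        q = rng.standard_normal(4)
        assert predict(back, q)[0] == predict(model, q)[0]

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "something-else"}')
        with pytest.raises(ValidationError):
            load_model(path)


def test_cross_validate_k_prefers_sane_k(rng):
    X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
    y = np.repeat(["A", "B"], 30)
    scores = cross_validate_k(X, y, k_grid=(1, 5), n_folds=3, seed=0)
    assert set(scores) == {1, 5}
    assert all(0.8 <= v <= 1.0 for v in scores.values())
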