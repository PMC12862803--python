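import numpy as np
import pytest
from scipy.spatial.distance import cdist

from molknn.knn import (
    build_index,
    calibration_curve,
    knn_predict,
    knn_predict_batch,
    loo_knn_predictions,
    mlkr_kernel_regression_predict,
    neighbor_quantiles,
    tune_k_loo,
)
from molknn.mlkr import MahalanobisMetric


class TestBuildIndexAndQuery:
    def test_three_points_on_line(self):
        index = build_index(points=[[0.0], [1.0], [2.0]])
        dist, idx = index.query([[1.0]], k=3)
        assert idx[0, 0] == 1 and dist[0, 0] == 0.0
        assert set(idx[0, 1:]) == {0, 2}

    def test_tree_and_brute_agree(self, rng):
        X = rng.normal(size=(500, 10))
        Q = rng.normal(size=(50, 10))
        brute = build_index(points=X, backend="brute")
        tree = build_index(points=X, backend="tree")
        db, ib = brute.query(Q, k=7)
        dt, it = tree.query(Q, k=7)
        np.testing.assert_array_equal(ib, it)
        np.testing.assert_allclose(db, dt, rtol=1e-12)

    def test_duplicate_points_tie_broken_by_index(self):
        X = [[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]]
        index = build_index(points=X)
        _, idx = index.query([[0.0, 0.0]], k=4)
        np.testing.assert_array_equal(idx[0], [0, 2, 1, 3])

    def test_tree_backend_rejected_for_kernel_induced(self):
        with pytest.raises(ValueError, match="tree"):
            build_index(distances=np.zeros((3, 3)), mode="kernel_induced",
                        backend="tree")

    def test_mahalanobis_mode_uses_transformed_space(self, rng):
        X = rng.normal(size=(20, 3))
        A = rng.normal(size=(2, 3))
        metric = MahalanobisMetric(A=A)
        index = build_index(points=X, mode="mahalanobis", metric=metric)
        q = rng.normal(size=(1, 3))
        dist, idx = index.query(q, k=3)
        D = cdist(q @ A.T, X @ A.T)
        np.testing.assert_allclose(dist[0], np.sort(D[0])[:3], rtol=1e-12)


class TestKnnPredict:
    def test_k1_returns_nearest_label(self):
        index = build_index(points=[[0.0], [1.0], [5.0]])
        y = [10.0, 20.0, 30.0]
        p = knn_predict(index, y, [0.2], k=1)
        assert p.estimate == 10.0
        assert p.neighbor_ids[0] == 0

    def test_uniform_k_equals_n_gives_global_mean(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        index = build_index(points=X)
        p = knn_predict(index, y, X[0], k=12, weighting="uniform")
        assert p.estimate == pytest.approx(y.mean())

    def test_reciprocal_equidistant_neighbors(self):
        index = build_index(points=[[0.0], [1.0], [2.0]])
        p = knn_predict(index, [0.0, 1.0, 2.0], [0.5], k=2,
                        weighting="reciprocal")
        assert p.estimate == pytest.approx(0.5)

    def test_zero_distance_takes_limit(self):
        index = build_index(points=[[0.0], [0.0], [3.0]])
        p = knn_predict(index, [1.0, 5.0, 100.0], [0.0], k=3,
                        weighting="reciprocal")
        assert p.estimate == pytest.approx(3.0)  # mean of zero-distance labels

    def test_estimate_within_neighbor_label_range(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        index = build_index(points=X)
        Q = rng.normal(size=(20, 4))
        for weighting in ("uniform", "reciprocal"):
            est, dist, idx = knn_predict_batch(index, y, Q, 5, weighting,
                                               return_neighbors=True)
            labels = np.asarray(y)[idx]
            assert np.all(est >= labels.min(axis=1) - 1e-12)
            assert np.all(est <= labels.max(axis=1) + 1e-12)

    def test_k_out_of_range_rejected(self):
        index = build_index(points=[[0.0], [1.0]])
        with pytest.raises(ValueError):
            knn_predict(index, [0.0, 1.0], [0.5], k=3)


class TestMlkrKernelRegression:
    def test_single_training_point_returns_its_label(self):
        metric = MahalanobisMetric(A=np.eye(2))
        est = mlkr_kernel_regression_predict(
            metric, np.array([[5.0, 5.0]]), [3.3], [[0.0, 0.0]]
        )
        assert est[0] == pytest.approx(3.3)

    def test_query_on_training_point_with_far_others(self):
        metric = MahalanobisMetric(A=np.eye(1), sigma=1.0)
        X = np.array([[0.0], [20.0], [30.0]])  # others at >= 10 sigma
        y = np.array([1.0, 100.0, 200.0])
        est = mlkr_kernel_regression_predict(metric, X, y, [[0.0]])
        assert est[0] == pytest.approx(1.0, abs=1e-4)

    def test_constant_labels_give_constant(self, rng):
        metric = MahalanobisMetric(A=np.eye(3))
        X = rng.normal(size=(10, 3))
        est = mlkr_kernel_regression_predict(metric, X, np.full(10, 7.0),
                                             rng.normal(size=(4, 3)))
        np.testing.assert_allclose(est, 7.0, rtol=1e-12)


class TestLooShortcut:
    def _explicit_loo(self, X, y, k, weighting):
        n = len(y)
        out = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            index = build_index(points=X[keep])
            p = knn_predict(index, y[keep], X[i], k=k, weighting=weighting)
            out[i] = p.estimate
        return out

    def test_uniform_shortcut_equals_explicit_requery(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        for k in range(1, 11):
            shortcut = loo_knn_predictions(X, y, k, weighting="uniform")
            explicit = self._explicit_loo(X, y, k, "uniform")
            np.testing.assert_allclose(shortcut, explicit, atol=1e-12)

    def test_reciprocal_drop_self_equals_explicit(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        shortcut = loo_knn_predictions(X, y, 5, weighting="reciprocal")
        explicit = self._explicit_loo(X, y, 5, "reciprocal")
        np.testing.assert_allclose(shortcut, explicit, atol=1e-12)

    def test_two_points_swap_labels(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([3.0, 8.0])
        np.testing.assert_allclose(
            loo_knn_predictions(X, y, 1, "uniform"), [8.0, 3.0]
        )


class TestTuneKLoo:
    def test_selected_k_on_plateau_for_smooth_data(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.0, 100.0, size=(2000, 1))
        y = np.sin(X[:, 0]) + rng.normal(scale=0.1, size=2000)
        best_k, loo = tune_k_loo(X, y, range(1, 31), weighting="uniform")
        assert 5 <= best_k <= 15
        plateau = [loo[k] for k in range(5, 16)]
        assert (max(plateau) - min(plateau)) / min(plateau) < 0.10

    def test_ties_resolve_to_smaller_k(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 1.0, 1.0, 1.0])  # every k gives zero error
        best_k, _ = tune_k_loo(X, y, [1, 2, 3], weighting="uniform")
        assert best_k == 1

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_k_loo(rng.normal(size=(5, 2)), rng.normal(size=5), [])


class TestNeighborQuantiles:
    def test_constant_labels_zero_width(self):
        q = neighbor_quantiles([4.0] * 7, [10, 25, 50, 75, 90])
        assert all(v == 4.0 for v in q.values())

    def test_linear_interpolation_definition(self):
        q = neighbor_quantiles([1.0, 2.0, 3.0, 4.0, 5.0], [25, 75])
        assert q[25.0] == pytest.approx(2.0)
        assert q[75.0] == pytest.approx(4.0)

    def test_median_of_three(self):
        q = neighbor_quantiles([1.0, 2.0, 3.0], [50])
        assert q[50.0] == 2.0

    def test_empty_percentiles_rejected(self):
        with pytest.raises(ValueError):
            neighbor_quantiles([1.0, 2.0], [])


class TestCalibrationCurve:
    def test_median_exact_truth(self, rng):
        # y_true equals each item's estimated median of distinct labels
        n = 30
        Q = np.sort(rng.normal(size=(n, 3)), axis=1)
        y_true = Q[:, 1]
        obs = calibration_curve(Q, y_true, [25, 50, 75])
        assert obs[1] == 1.0
        assert obs[0] == 0.0

    def test_monotone_in_percentile(self, rng):
        labels = rng.normal(size=(100, 21))
        grid = [10, 30, 50, 70, 90]
        Q = np.stack(
            [
                [neighbor_quantiles(row, [p])[float(p)] for p in grid]
                for row in labels
            ]
        )
        obs = calibration_curve(Q, rng.normal(size=100), grid)
        assert np.all(np.diff(obs) >= 0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            calibration_curve(rng.normal(size=(5, 2)), rng.normal(size=4), [25, 75])
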