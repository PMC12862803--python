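import numpy as np
import pytest

from molknn.evaluate import (
    EvaluationPlan,
    Features,
    ModelSpec,
    cross_validate,
    delta_targets,
    extrapolation_split,
    fit_predict,
    mae,
    tune_knn_k,
    tune_krr_hyperparams,
)
from molknn.structures import LabeledDataset


class TestMae:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=10)
        assert mae(y, y) == 0.0

    def test_hand_example(self):
        assert mae([0.0, 2.0], [1.0, 1.0]) == 1.0

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        oracle = sum(abs(x - z) for x, z in zip(a, b)) / 50
        assert mae(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestDeltaTargets:
    def test_equal_levels_give_zero_residuals(self, cluster_dataset):
        ds = LabeledDataset(
            cluster_dataset.structures,
            y_high=cluster_dataset.y_high,
            y_low=cluster_dataset.y_high.copy(),
        )
        np.testing.assert_array_equal(delta_targets(ds), 0.0)

    def test_exact_residual_model_recovers_labels(self, cluster_dataset):
        resid = delta_targets(cluster_dataset)
        final = cluster_dataset.y_low + resid
        assert mae(cluster_dataset.y_high, final) == 0.0

    def test_missing_low_level_rejected(self, cluster_dataset):
        ds = LabeledDataset(cluster_dataset.structures,
                            y_high=cluster_dataset.y_high)
        with pytest.raises(ValueError, match="y_low"):
            delta_targets(ds)


class TestCrossValidate:
    def test_folds_partition_dataset(self, cluster_dataset, light_params):
        from molknn._util import substream

        n = len(cluster_dataset)
        perm = substream(3, "cv-folds").permutation(n)
        folds = np.array_split(perm, 5)
        assert sum(len(f) for f in folds) == n
        assert len(np.unique(np.concatenate(folds))) == n

    def test_deterministic_given_seed(self, cluster_dataset, light_params):
        plan = EvaluationPlan(
            model=ModelSpec(name="knn_euclidean", k=3),
            train_sizes=(30,), seed=11, descriptor=light_params,
        )
        r1 = cross_validate(cluster_dataset, plan)
        r2 = cross_validate(cluster_dataset, plan)
        np.testing.assert_array_equal(r1["mae"].to_numpy(), r2["mae"].to_numpy())

    def test_constant_mean_predictor_matches_fold_oracle(
        self, cluster_dataset, light_params
    ):
        # uniform k-NN with k = train_size predicts the training mean
        size = 30
        plan = EvaluationPlan(
            model=ModelSpec(name="knn_euclidean", k=size, weighting="uniform"),
            train_sizes=(size,), seed=7, descriptor=light_params,
        )
        res = cross_validate(cluster_dataset, plan)
        from molknn._util import substream

        n = len(cluster_dataset)
        perm = substream(7, "cv-folds").permutation(n)
        folds = np.array_split(perm, 5)
        for fold_id, test_idx in enumerate(folds):
            rest = np.setdiff1d(perm, test_idx, assume_unique=True)
            rng = substream(7, f"subsample-f{fold_id}-s{size}")
            train_idx = rng.choice(rest, size=size, replace=False)
            expected = mae(
                cluster_dataset.y_high[test_idx],
                np.full(len(test_idx), cluster_dataset.y_high[train_idx].mean()),
            )
            got = res[(res["fold"] == fold_id)]["mae"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_oversized_train_size_rejected(self, cluster_dataset, light_params):
        plan = EvaluationPlan(
            model=ModelSpec(name="knn_euclidean"), train_sizes=(75,),
            seed=0, descriptor=light_params,
        )
        with pytest.raises(ValueError, match="train_size"):
            cross_validate(cluster_dataset, plan)


class TestExtrapolationSplit:
    def test_partition_by_composition(self, cluster_dataset):
        holdout = {"SA": 3, "W": 3}
        train, test = extrapolation_split(cluster_dataset, holdout)
        assert len(train) + len(test) == len(cluster_dataset)
        assert all(s.composition == holdout for s in test.structures)
        assert all(s.composition != holdout for s in train.structures)

    def test_absent_composition_raises_with_name(self, cluster_dataset):
        with pytest.raises(ValueError, match=r"\(SA\)9\(W\)9"):
            extrapolation_split(cluster_dataset, {"SA": 9, "W": 9})


class TestTuning:
    def test_single_point_grids_returned(self, cluster_dataset, light_params):
        sigma, lam = tune_krr_hyperparams(
            cluster_dataset, sigma_grid=[3.0], lambda_grid=[1e-6],
            seed=0, descriptor=light_params,
        )
        assert (sigma, lam) == (3.0, 1e-6)

    def test_krr_tuning_deterministic(self, cluster_dataset, light_params):
        grids = dict(sigma_grid=[2.0, 8.0], lambda_grid=[1e-8, 1e-4])
        a = tune_krr_hyperparams(cluster_dataset, seed=5,
                                 descriptor=light_params, **grids)
        b = tune_krr_hyperparams(cluster_dataset, seed=5,
                                 descriptor=light_params, **grids)
        assert a == b

    def test_krr_sigma_choice_matches_exhaustive_oracle(
        self, cluster_dataset, light_params
    ):
        sigma_grid = [1.0, 5.0, 25.0]
        lambda_grid = [1e-8]
        chosen_sigma, _ = tune_krr_hyperparams(
            cluster_dataset, sigma_grid=sigma_grid, lambda_grid=lambda_grid,
            seed=2, descriptor=light_params,
        )
        # exhaustive oracle: recompute every validation MAE independently
        from molknn._util import substream
        from molknn.kernels import KernelSpec, kernel_matrix
        from molknn.krr import krr_fit, krr_predict

        n = len(cluster_dataset)
        n_train = (n * 4) // 5
        perm = substream(2, "krr-tune-split").permutation(n)
        idx_tr, idx_va = perm[:n_train], perm[n_train:]
        feats = Features(cluster_dataset, light_params)
        scores = {}
        for s in sigma_grid:
            spec = KernelSpec(kind="extensive_atomic", sigma=s)
            reps_tr = [feats.local[i] for i in idx_tr]
            reps_va = [feats.local[i] for i in idx_va]
            K = kernel_matrix(reps_tr, reps_tr, spec)
            model = krr_fit(K, cluster_dataset.y_high[idx_tr], 1e-8)
            pred = krr_predict(model, kernel_matrix(reps_va, reps_tr, spec))
            scores[s] = mae(cluster_dataset.y_high[idx_va], pred)
        assert chosen_sigma == min(sigma_grid, key=lambda s: scores[s])

    def test_knn_k_single_grid(self, cluster_dataset, light_params):
        spec = ModelSpec(name="knn_euclidean")
        assert tune_knn_k(cluster_dataset, spec, k_grid=[1], seed=0,
                          descriptor=light_params) == 1

    def test_knn_k_deterministic(self, cluster_dataset, light_params):
        spec = ModelSpec(name="knn_euclidean")
        a = tune_knn_k(cluster_dataset, spec, k_grid=[1, 3, 5], seed=4,
                       descriptor=light_params)
        b = tune_knn_k(cluster_dataset, spec, k_grid=[1, 3, 5], seed=4,
                       descriptor=light_params)
        assert a == b


def test_fit_predict_all_models_run(cluster_dataset, light_params):
    feats = Features(cluster_dataset, light_params)
    n = len(cluster_dataset)
    idx_tr, idx_te = np.arange(0, 60), np.arange(60, n)
    for name in ("krr", "knn_euclidean", "knn_mlkr", "knn_kernel_distance",
                 "kernel_regression_mlkr"):
        spec = ModelSpec(name=name, k=5, mlkr_max_iter=20)
        pred, fit_s, pred_s = fit_predict(
            spec, feats, cluster_dataset.y_high, idx_tr, idx_te, seed=0
        )
        assert pred.shape == (len(idx_te),)
        assert np.all(np.isfinite(pred))
        assert fit_s >= 0 and pred_s >= 0
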