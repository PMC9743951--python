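import numpy as np
import pytest

from sparsecf.core import RatingsMatrix, mask_random
from sparsecf.models import (
    GLOBAL_MEAN_FALLBACK,
    ITEM_MEAN_FALLBACK,
    ImputationError,
    KNNFit,
    NNMFFit,
    knn_fit,
    knn_predict,
    mean_predict,
    mice_impute,
    mult_update,
    nnmf_mult_fit,
    nnmf_predict,
    nnmf_sgd_fit,
)
from sparsecf.models import _sgd_epoch
from sparsecf.similarity import SimilarityMatrix

from conftest import random_matrix


class TestMeanPredict:
    def test_column_mean(self):
        v = np.array([[1.0, np.nan], [3.0, np.nan], [np.nan, 5.0]])
        m = RatingsMatrix(list("abc"), ["x", "y"], v)
        preds = mean_predict(m, [(2, 0)])
        assert preds[0].value == 2.0
        assert preds[0].method_used == "model"

    def test_empty_column_falls_back_to_global_mean(self):
        v = np.array([[5.0, np.nan], [5.0, np.nan]])
        m = RatingsMatrix(["a", "b"], ["x", "y"], v)
        preds = mean_predict(m, [(0, 1)])
        assert preds[0].value == 5.0
        assert preds[0].method_used == GLOBAL_MEAN_FALLBACK

    def test_matches_column_mean_oracle_everywhere(self):
        m = random_matrix(9, 7, 0.0, seed=2)
        cells = np.argwhere(np.ones_like(m.values, dtype=bool))
        preds = mean_predict(m, cells).values.reshape(9, 7)
        oracle = np.tile(m.values.mean(axis=0), (9, 1))
        np.testing.assert_allclose(preds, oracle, atol=1e-12)


class TestKnnPredict:
    def test_weighted_aggregation_excludes_negative_similarity(self):
        # similarities to the target: 1.0, 0.5, -0.2; ratings 10, 4, 100
        sim = np.array(
            [
                [1.0, 1.0, 0.5, -0.2],
                [1.0, 1.0, 0.0, 0.0],
                [0.5, 0.0, 1.0, 0.0],
                [-0.2, 0.0, 0.0, 1.0],
            ]
        )
        v = np.array(
            [
                [np.nan, 1.0, 1.0, 1.0],
                [10.0, 1.0, np.nan, np.nan],
                [4.0, np.nan, 1.0, np.nan],
                [100.0, np.nan, np.nan, 1.0],
            ]
        )
        train = RatingsMatrix(list("uvwx"), list("abcd"), v)
        fit = KNNFit(train, SimilarityMatrix(list("uvwx"), sim, "pearson", 2), k=10)
        preds = knn_predict(fit, [(0, 0)])
        assert preds[0].value == pytest.approx((1.0 * 10 + 0.5 * 4) / 1.5)

    def test_single_neighbor_weight_cancels(self):
        sim = np.array([[1.0, 0.9], [0.9, 1.0]])
        v = np.array([[np.nan, 1.0], [42.0, 2.0]])
        train = RatingsMatrix(["u", "v"], ["a", "b"], v)
        fit = KNNFit(train, SimilarityMatrix(["u", "v"], sim, "pearson", 2), k=10)
        assert knn_predict(fit, [(0, 0)])[0].value == pytest.approx(42.0)

    def test_no_candidates_falls_back_to_item_mean(self):
        # user u anticorrelated with everyone -> no positive similarity
        v = np.array([[1.0, 2.0, 3.0, np.nan], [3.0, 2.0, 1.0, 7.0], [3.0, 2.0, 1.0, 9.0]])
        train = RatingsMatrix(list("uvw"), list("abcd"), v)
        preds = knn_predict(knn_fit(train, k=10), [(0, 3)])
        assert preds[0].method_used == ITEM_MEAN_FALLBACK
        assert preds[0].value == pytest.approx(8.0)

    def test_k_limits_neighbor_count(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 10, 8)
        v = np.vstack([base + rng.normal(0, 0.1, 8) for _ in range(5)])
        v[0, 0] = np.nan
        train = RatingsMatrix(list("abcde"), [f"i{k}" for k in range(8)], v)
        fit1 = knn_fit(train, k=1)
        # with k=1 prediction equals the single most similar user's rating
        best = np.nanargmax(np.where(np.arange(5) == 0, -np.inf, fit1.similarity.values[0]))
        assert knn_predict(fit1, [(0, 0)])[0].value == pytest.approx(train.values[best, 0])

    def test_rejects_k_below_one(self):
        train = random_matrix(4, 6, 0.0, 1)
        with pytest.raises(ValueError):
            knn_fit(train, k=0)


class TestNnmfSgd:
    def test_single_bias_update_arithmetic(self):
        # one observed cell, value 10; mu, biases and factors all zero
        rows = np.array([0], dtype=np.int64)
        cols = np.array([0], dtype=np.int64)
        vals = np.array([10.0])
        order = np.array([0], dtype=np.int64)
        b_u = np.zeros(1)
        b_i = np.zeros(1)
        W = np.zeros((1, 2))
        H = np.zeros((2, 1))
        _sgd_epoch(rows, cols, vals, order, 0.0, b_u, b_i, W, H, 0.001, 0.0, 0.0, 0.0, 0.0)
        assert b_i[0] == pytest.approx(0.01)
        assert b_u[0] == pytest.approx(0.01)

    def test_tiny_gamma_predicts_global_mean(self):
        m = random_matrix(6, 8, 0.2, seed=4)
        # initial factor products are O(1/f), so predictions start near mu
        fit = nnmf_sgd_fit(m, f=64, gamma=1e-12, max_iter=3, tol=0.0, seed=0)
        cells = np.argwhere(np.isfinite(m.values))
        preds = nnmf_predict(fit, cells).values
        np.testing.assert_allclose(preds, fit.mu, atol=0.1)
        assert fit.mu == pytest.approx(np.nanmean(m.values))

    def test_bit_reproducible_under_fixed_seed(self):
        m = random_matrix(8, 10, 0.3, seed=5)
        a = nnmf_sgd_fit(m, f=3, max_iter=20, tol=0.0, seed=123)
        b = nnmf_sgd_fit(m, f=3, max_iter=20, tol=0.0, seed=123)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        assert a.history == b.history

    def test_factors_stay_nonnegative(self):
        m = random_matrix(10, 12, 0.3, seed=6)
        fit = nnmf_sgd_fit(m, f=4, max_iter=50, tol=0.0, seed=0)
        assert fit.W.min() >= 0.0
        assert fit.H.min() >= 0.0

    def test_history_decreases_then_stops_on_tolerance(self):
        m = random_matrix(10, 12, 0.0, seed=7)
        fit = nnmf_sgd_fit(m, f=2, tol=1.0, max_iter=500, seed=0)
        assert fit.converged
        assert fit.history[0] > fit.history[-1]

    def test_learning_rate_blowup_raises(self):
        m = random_matrix(10, 12, 0.0, seed=8)
        with pytest.raises(FloatingPointError):
            nnmf_sgd_fit(m, f=3, gamma=5.0, max_iter=50, tol=0.0, seed=0)

    def test_predict_arithmetic(self):
        fit = NNMFFit(
            mu=50.0, b_u=np.array([2.0]), b_i=np.array([-3.0]),
            W=np.array([[1.0]]), H=np.array([[1.0]]), gamma=0.001,
            lambdas=(0, 0, 0, 0), f=1, history=[], seed=0, converged=True,
        )
        assert nnmf_predict(fit, [(0, 0)])[0].value == pytest.approx(50.0)


class TestNnmfMult:
    def test_exact_factorization_is_fixed_point(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.5, 2.0, (6, 2))
        H = rng.uniform(0.5, 2.0, (2, 8))
        V = W @ H
        W2, H2 = mult_update(V, W.copy(), H.copy())
        assert np.abs(W2 - W).max() < 1e-10
        assert np.abs(H2 - H).max() < 1e-10

    def test_rank_one_reconstruction(self):
        rng = np.random.default_rng(1)
        V = np.outer(rng.uniform(1, 5, 10), rng.uniform(1, 5, 12))
        m = RatingsMatrix([f"u{i}" for i in range(10)], [f"i{j}" for j in range(12)], V)
        fit = nnmf_mult_fit(m, f=1, max_iter=2000, tol=1e-12, seed=0)
        recon_rmse = np.sqrt(fit.history[-1])
        assert recon_rmse < 0.01 * (V.max() - V.min())

    def test_negative_data_requires_scale(self):
        v = np.array([[-1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError):
            nnmf_mult_fit(RatingsMatrix(["a", "b"], ["x", "y"], v), f=1)
        shifted = nnmf_mult_fit(
            RatingsMatrix(["a", "b"], ["x", "y"], v, scale=(-5, 5)), f=2, max_iter=50, seed=0
        )
        assert shifted.mu == -5.0  # the non-negativity shift rides in mu


class TestMice:
    def test_identity_on_fully_observed(self):
        m = random_matrix(8, 5, 0.0, seed=9)
        out = mice_impute(m, seed=0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_recovers_exact_linear_relation(self):
        rng = np.random.default_rng(3)
        # the missing B value must sit inside the observed range, or the
        # final clipping step (correctly) truncates it
        a = np.array([1.0, 2.0, 5.0, 7.0, 9.0, 4.0])
        c = rng.uniform(0, 10, 6)
        v = np.column_stack([a, 2 * a, c])
        v[2, 1] = np.nan
        m = RatingsMatrix([f"u{i}" for i in range(6)], ["A", "B", "C"], v)
        out = mice_impute(m, seed=0)
        assert out.values[2, 1] == pytest.approx(2 * a[2], abs=1e-8)

    def test_imputations_clipped_to_observed_range(self):
        # B is strongly increasing in A; the missing B row has the largest A,
        # so the regression extrapolates above the observed maximum
        a = np.array([0.0, 1, 2, 3, 4, 10.0])
        b = 2 * a
        b_obs = b.copy()
        b_obs[-1] = np.nan
        v = np.column_stack([a, b_obs, np.array([1.0, 0, 1, 0, 1, 0])])
        m = RatingsMatrix([f"u{i}" for i in range(6)], ["A", "B", "C"], v)
        out = mice_impute(m, seed=0)
        assert out.values[-1, 1] == pytest.approx(10.0)  # observed max

    def test_failure_on_empty_column(self):
        v = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ImputationError):
            mice_impute(RatingsMatrix(["a", "b"], ["x", "y"], v), seed=0)

    def test_failure_on_single_observed_row(self):
        v = np.array([[1.0, 5.0], [2.0, np.nan], [3.0, np.nan]])
        with pytest.raises(ImputationError):
            mice_impute(RatingsMatrix(list("abc"), ["x", "y"], v), seed=0)


class TestFallbacksUnderExtremeSparsity:
    def test_user_with_no_train_ratings_still_gets_predictions(self):
        m = random_matrix(10, 10, 0.0, seed=10)
        # mask everything a specific user rated
        split = mask_random(m, 0.9, seed=0)
        train = split.train_matrix(m)
        cells = split.test_cells()
        for preds in (
            mean_predict(train, cells),
            knn_predict(knn_fit(train, k=10), cells),
            nnmf_predict(nnmf_sgd_fit(train, f=2, max_iter=10, tol=0.0, seed=0), cells),
        ):
            assert np.all(np.isfinite(preds.values))
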