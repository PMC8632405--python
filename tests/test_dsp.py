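import numpy as np
import pytest
import scipy.linalg

from dspline.data_model import EpochSet
from dspline.dsp import (
    DspModel,
    VectorizedTrials,
    devectorize,
    dsp_classic,
    dsp_improved,
    fisher_criterion,
    load_model,
    ridge_solve_lowrank,
    save_model,
    scatter_matrices,
    transform,
    vectorize,
)

from conftest import random_vectorized


class TestVectorize:
    def test_flattening_convention(self):
        epochs = EpochSet(trials=[np.array([[1.0, 2, 3], [4, 5, 6]])],
                          labels=["x"], channel_names=["a", "b"],
                          sampling_rate=500.0)
        v = vectorize(epochs)
        np.testing.assert_array_equal(v.vectors[0], [1, 2, 3, 4, 5, 6])
        assert v.dims == (2, 3)

    def test_round_trip(self, random_epochs):
        epochs = random_epochs(n_trials=3)
        v = vectorize(epochs)
        for i, trial in enumerate(epochs.trials):
            np.testing.assert_array_equal(
                devectorize(v.vectors[i], v.dims), trial)

    def test_paper_scale_dimension(self):
        epochs = EpochSet(trials=[np.zeros((60, 182))], labels=["x"],
                          channel_names=[f"e{i}" for i in range(60)],
                          sampling_rate=500.0)
        assert vectorize(epochs).n_features == 10920

    def test_empty_fatal(self):
        epochs = EpochSet(trials=[], labels=[], channel_names=["a"],
                          sampling_rate=500.0)
        with pytest.raises(ValueError):
            vectorize(epochs)


class TestScatterMatrices:
    def test_toy_values(self, toy_scatter):
        np.testing.assert_allclose(toy_scatter.s_w, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(toy_scatter.s_b, [[1, 1], [1, 1]])
        np.testing.assert_allclose(toy_scatter.grand_mean, [0, 0])
        np.testing.assert_allclose(toy_scatter.class_means,
                                   [[0.5, 0.5], [-0.5, -0.5]])

    def test_toy_total_scatter_identity(self, toy_vectors, toy_scatter):
        total = sum(np.outer(x, x) for x in toy_vectors.vectors)
        np.testing.assert_allclose(total, [[2, 0], [0, 2]])
        np.testing.assert_allclose(toy_scatter.s_w + toy_scatter.s_b, total,
                                   atol=1e-12)

    def test_equal_means_give_zero_between(self):
        v = VectorizedTrials(
            vectors=np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]),
            labels=["A", "A", "B", "B"], dims=(1, 2))
        s = scatter_matrices(v, reg_gamma=0.1)
        np.testing.assert_allclose(s.s_b, np.zeros((2, 2)), atol=1e-12)

    def test_single_class_fatal(self):
        v = VectorizedTrials(vectors=np.eye(3), labels=["A"] * 3, dims=(1, 3))
        with pytest.raises(ValueError, match="2 classes"):
            scatter_matrices(v)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instance_invariants(self, seed):
        rng = np.random.default_rng(seed)
        v = random_vectorized(rng, n_per_class=(7, 5, 4), dim=6)
        s = scatter_matrices(v, reg_gamma=1e-3)
        np.testing.assert_allclose(s.s_w, s.s_w.T, atol=1e-10)
        np.testing.assert_allclose(s.s_b, s.s_b.T, atol=1e-10)
        scale = np.mean(np.diag(s.s_w))
        assert np.linalg.eigvalsh(s.s_w).min() >= -1e-10 * scale
        assert np.linalg.eigvalsh(s.s_b).min() >= -1e-10 * scale
        # rank(S_B) <= K - 1
        assert np.linalg.matrix_rank(s.s_b, tol=1e-8 * scale) <= 2
        grand = v.vectors.mean(axis=0)
        total = (v.vectors - grand).T @ (v.vectors - grand)
        np.testing.assert_allclose(s.s_w + s.s_b, total, rtol=1e-8)

    def test_zero_sum_identity(self):
        rng = np.random.default_rng(99)
        v = random_vectorized(rng, n_per_class=(9, 3, 6), dim=8)
        s = scatter_matrices(v)
        np.testing.assert_allclose(s.class_offsets().sum(axis=0),
                                   np.zeros(8), atol=1e-10)


class TestFisherCriterion:
    def test_toy_value(self, toy_scatter):
        # ridge = 0.1: numerator 4, denominator 0.2
        J = fisher_criterion(np.array([[1.0], [1.0]]), toy_scatter)
        assert J == pytest.approx(20.0, rel=1e-12)

    def test_scale_invariance(self, toy_scatter):
        w = np.array([[1.0], [0.3]])
        assert fisher_criterion(3.7 * w, toy_scatter) == pytest.approx(
            fisher_criterion(w, toy_scatter), rel=1e-10)

    def test_null_direction(self, toy_scatter):
        assert fisher_criterion(np.array([[1.0], [-1.0]]),
                                toy_scatter) == pytest.approx(0.0, abs=1e-12)


class TestDspClassic:
    def test_toy_leading_direction(self, toy_scatter):
        model = dsp_classic(toy_scatter, m=2)
        np.testing.assert_allclose(np.abs(model.W1[:, 0]),
                                   [1 / np.sqrt(2)] * 2, rtol=1e-10)
        assert model.eigenvalues[0] > 0
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_real_nonnegative_spectrum(self, seed):
        rng = np.random.default_rng(seed)
        v = random_vectorized(rng, n_per_class=(8, 8, 8), dim=6)
        s = scatter_matrices(v, reg_gamma=1e-3)
        model = dsp_classic(s, m=6)
        assert np.isrealobj(model.eigenvalues)
        assert model.eigenvalues.min() >= -1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_generalized_eigensolver(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = random_vectorized(rng, n_per_class=(10, 9, 8), dim=6)
        s = scatter_matrices(v, reg_gamma=1e-3)
        model = dsp_classic(s, m=1)
        ridge = s.ridge
        evals, evecs = scipy.linalg.eigh(
            s.s_b, s.s_w + ridge * np.eye(6))
        oracle = evecs[:, -1] / np.linalg.norm(evecs[:, -1])
        cos = abs(model.W1[:, 0] @ oracle)
        assert cos > 1 - 1e-8

    def test_gamma_zero_with_singular_sw_fatal(self):
        # two trials per class in 3-D: S_W singular
        v = VectorizedTrials(
            vectors=np.array([[1.0, 0, 0], [1, 1, 0],
                              [-1, 0, 0], [-1, 1, 0]]),
            labels=["A", "A", "B", "B"], dims=(1, 3))
        s = scatter_matrices(v, reg_gamma=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="reg_gamma"):
            dsp_classic(s, m=1)


class TestDspImproved:
    def test_toy_directions_per_class(self, toy_scatter):
        model = dsp_improved(toy_scatter)
        assert model.W1.shape == (2, 2)
        for j in range(2):
            np.testing.assert_allclose(model.W1[:, j],
                                       [1 / np.sqrt(2)] * 2, rtol=1e-10)
        assert model.class_order == ["A", "B"]

    @pytest.mark.parametrize("seed", range(10))
    def test_k2_matches_classic_eigenvector(self, seed):
        rng = np.random.default_rng(200 + seed)
        v = random_vectorized(rng, n_per_class=(12, 9), dim=5)
        s = scatter_matrices(v, reg_gamma=1e-3)
        improved = dsp_improved(s)
        classic = dsp_classic(s, m=1)
        for j in range(2):
            cos = abs(improved.W1[:, j] @ classic.W1[:, 0])
            assert cos >= 1 - 1e-6

    def test_scale_invariance_of_directions(self, rng):
        v = random_vectorized(rng, n_per_class=(8, 8), dim=4)
        scaled = VectorizedTrials(vectors=137.0 * v.vectors, labels=v.labels,
                                  dims=v.dims)
        m1 = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        m2 = dsp_improved(scatter_matrices(scaled, reg_gamma=1e-3))
        np.testing.assert_allclose(np.abs(np.sum(m1.W1 * m2.W1, axis=0)),
                                   np.ones(2), rtol=1e-8)

    def test_unit_norm_and_sign_convention(self, rng):
        v = random_vectorized(rng, n_per_class=(6, 7, 5), dim=6)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        norms = np.linalg.norm(model.W1, axis=0)
        np.testing.assert_allclose(norms, np.ones(3), rtol=1e-12)
        for j in range(3):
            i = np.argmax(np.abs(model.W1[:, j]))
            assert model.W1[i, j] > 0

    def test_gamma_zero_fatal(self, toy_vectors):
        s = scatter_matrices(toy_vectors, reg_gamma=0.0)
        with pytest.raises(ValueError, match="reg_gamma"):
            dsp_improved(s)


class TestLowRankSolve:
    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_dense(self, seed):
        rng = np.random.default_rng(300 + seed)
        n, D = 30, 200
        centered = rng.normal(size=(n, D))
        ridge = 0.5
        B = rng.normal(size=(D, 2))
        X = ridge_solve_lowrank(centered, ridge, B)
        dense = np.linalg.solve(centered.T @ centered + ridge * np.eye(D), B)
        np.testing.assert_allclose(X, dense, rtol=1e-8, atol=1e-10)

    def test_improved_lowrank_route_matches_dense_route(self, rng):
        v = random_vectorized(rng, n_per_class=(15, 12), dim=40)
        s_dense = scatter_matrices(v, reg_gamma=1e-3, materialize=True)
        s_lazy = scatter_matrices(v, reg_gamma=1e-3, materialize=False)
        assert s_lazy.s_w is None
        m_dense = dsp_improved(s_dense, method="dense")
        m_lazy = dsp_improved(s_lazy, method="lowrank")
        np.testing.assert_allclose(m_lazy.W1, m_dense.W1, rtol=1e-6)

    def test_nonpositive_ridge_fatal(self, rng):
        with pytest.raises(ValueError):
            ridge_solve_lowrank(rng.normal(size=(4, 8)), 0.0,
                                rng.normal(size=8))


class TestTransform:
    def test_dot_product_example(self):
        w = np.array([[1.0], [1.0]]) / np.sqrt(2)
        model = DspModel(W1=w, delta=np.zeros(1), grand_mean=np.zeros(2),
                         dims=(1, 2), backend="improved", reg_gamma=1e-3)
        v = VectorizedTrials(vectors=np.array([[1.0, 0.0]]), labels=["x"],
                             dims=(1, 2))
        feats = transform(model, v)
        assert feats.matrix[0, 0] == pytest.approx(1 / np.sqrt(2))

    def test_fitted_features_are_centered(self, rng):
        v = random_vectorized(rng, n_per_class=(10, 8), dim=6)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        feats = transform(model, v)
        np.testing.assert_allclose(feats.matrix.mean(axis=0), np.zeros(2),
                                   atol=1e-10)

    def test_grand_mean_maps_to_zero(self, rng):
        v = random_vectorized(rng, n_per_class=(10, 8), dim=6)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        vm = VectorizedTrials(vectors=model.grand_mean[None, :], labels=["m"],
                              dims=v.dims)
        feats = transform(model, vm)
        np.testing.assert_allclose(feats.matrix[0], np.zeros(2), atol=1e-12)

    def test_dimension_mismatch_fatal(self, rng):
        v = random_vectorized(rng, n_per_class=(5, 5), dim=6)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        bad = VectorizedTrials(vectors=np.zeros((2, 4)), labels=["a", "b"],
                               dims=(1, 4))
        with pytest.raises(ValueError, match="dimension"):
            transform(model, bad)


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        v = random_vectorized(rng, n_per_class=(8, 8), dim=5)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        path = save_model(model, tmp_path / "model.json")
        back = load_model(path)
        np.testing.assert_array_equal(back.W1, model.W1)
        np.testing.assert_array_equal(back.delta, model.delta)
        assert back.backend == model.backend
        assert back.class_order == model.class_order
        assert back.dims == model.dims

    def test_unknown_schema_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"schema": "other"}')
        with pytest.raises(ValueError):
            load_model(p)
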