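"""SE-ARD kernel algebra and exact GP regression against dense oracles."""

import numpy as np
import pytest

from gpmoe.gp_expert import (
    ARDKernelParams,
    GPExpertModel,
    ard_kernel,
    fit_gp_expert,
    kernel_matrix,
    load_expert,
    nlml,
    posterior_predict,
    save_expert,
    _nlml_value_grad,
)

LOG_2PI = np.log(2 * np.pi)


def dense_posterior(X, Y, Xs, params, noise):
    """Brute-force posterior mean/variance via explicit matrix inversion."""
    K = kernel_matrix(X, None, params)
    A_inv = np.linalg.inv(K + noise * np.eye(len(X)))
    Ks = kernel_matrix(Xs, X, params)
    mean = Ks @ A_inv @ Y
    var = params.variance - np.einsum("ij,jk,ik->i", Ks, A_inv, Ks)
    return mean, var


def dense_nlml(X, Y, params, noise):
    """Direct dense formula: quadratic + log-determinant + constant."""
    A = kernel_matrix(X, None, params) + noise * np.eye(len(X))
    A_inv = np.linalg.inv(A)
    sign, logdet = np.linalg.slogdet(A)
    assert sign > 0
    m = Y.shape[1]
    return (
        0.5 * float(np.einsum("ic,ij,jc->", Y, A_inv, Y))
        + 0.5 * m * logdet
        + 0.5 * m * len(X) * LOG_2PI
    )


class TestARDKernel:
    def test_zero_distance_is_variance(self, rng):
        p = ARDKernelParams(2.5, rng.uniform(0.5, 2, 4))
        x = rng.normal(size=4)
        assert ard_kernel(x, x, p) == pytest.approx(2.5)

    def test_isotropic_reduction(self, rng):
        x, x2 = rng.normal(size=3), rng.normal(size=3)
        aniso = ard_kernel(x, x2, ARDKernelParams(1.3, np.full(3, 0.7)))
        iso = 1.3 * np.exp(-np.sum((x - x2) ** 2) / (2 * 0.7**2))
        assert aniso == pytest.approx(iso, rel=1e-12)

    def test_hand_value(self):
        p = ARDKernelParams(1.0, np.array([1.0, 2.0]))
        val = ard_kernel(np.array([0.0, 0.0]), np.array([1.0, 2.0]), p)
        assert val == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_dimension_mismatch(self):
        p = ARDKernelParams(1.0, np.ones(2))
        with pytest.raises(ValueError):
            ard_kernel(np.zeros(3), np.zeros(3), p)

    def test_symmetry_and_bounds(self, rng):
        p = ARDKernelParams(2.0, rng.uniform(0.3, 3, 5))
        x, x2 = rng.normal(size=5), rng.normal(size=5)
        k = ard_kernel(x, x2, p)
        assert k == pytest.approx(ard_kernel(x2, x, p))
        assert 0 < k <= 2.0


class TestKernelMatrix:
    def test_symmetric_with_variance_diagonal(self, rng):
        p = ARDKernelParams(1.7, rng.uniform(0.5, 2, 3))
        K = kernel_matrix(rng.normal(size=(6, 3)), None, p, jitter=0.01)
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(np.diag(K), 1.7 + 0.01)

    def test_single_point(self):
        p = ARDKernelParams(0.9, np.ones(2))
        K = kernel_matrix(np.zeros((1, 2)), None, p)
        np.testing.assert_allclose(K, [[0.9]])

    def test_positive_definite_after_jitter(self, rng):
        p = ARDKernelParams(1.0, rng.uniform(0.5, 2, 3))
        K = kernel_matrix(rng.normal(size=(5, 3)), None, p, jitter=1e-8)
        assert np.linalg.eigvalsh(K).min() > 0


class TestNLML:
    def test_closed_form_single_point(self):
        # k(x,x)=0.5, noise=0.5 -> A=[1]; y=0 -> NLML = 1/2 log 2pi
        model = GPExpertModel(
            ARDKernelParams(0.5, np.ones(1)), 0.5, np.zeros((1, 1)), np.zeros((1, 1))
        )
        assert nlml(model) == pytest.approx(0.5 * LOG_2PI, abs=1e-9)
        assert nlml(model) == pytest.approx(0.9189385, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_formula(self, seed):
        rng = np.random.default_rng(seed)
        n, d, m = rng.integers(3, 15), rng.integers(1, 5), rng.integers(1, 4)
        X, Y = rng.normal(size=(n, d)), rng.normal(size=(n, m))
        p = ARDKernelParams(rng.uniform(0.5, 2), rng.uniform(0.5, 2, d))
        noise = rng.uniform(0.05, 0.5)
        model = GPExpertModel(p, noise, X, Y)
        assert nlml(model) == pytest.approx(dense_nlml(X, Y, p, noise), abs=1e-8)
        # per-column values sum to the total
        total = sum(nlml(model, c) for c in range(m))
        assert total == pytest.approx(nlml(model), abs=1e-8)

    def test_doubling_targets_quadruples_quadratic_term(self, rng):
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 1))
        p = ARDKernelParams(1.0, np.ones(2))
        m1 = GPExpertModel(p, 0.2, X, Y)
        m2 = GPExpertModel(p, 0.2, X, 2 * Y)
        A_inv = np.linalg.inv(kernel_matrix(X, None, p) + 0.2 * np.eye(8))
        quad = 0.5 * float((Y.T @ A_inv @ Y).item())
        assert nlml(m2) - nlml(m1) == pytest.approx(3 * quad, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 10, 3
        X, Y = rng.normal(size=(n, d)), rng.normal(size=(n, 2))
        D = np.ascontiguousarray(
            np.moveaxis((X[:, None, :] - X[None, :, :]) ** 2, 2, 0)
        )
        theta = rng.normal(scale=0.3, size=d + 2)
        _, grad = _nlml_value_grad(theta, X, Y, D)
        for i in range(theta.size):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            num = (
                _nlml_value_grad(theta + e, X, Y, D)[0]
                - _nlml_value_grad(theta - e, X, Y, D)[0]
            ) / 2e-6
            assert grad[i] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestPosteriorPredict:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(10, 2))
        p = ARDKernelParams(rng.uniform(0.5, 2), rng.uniform(0.5, 2, 3))
        noise = rng.uniform(0.05, 0.3)
        model = GPExpertModel(p, noise, X, Y)
        Xs = rng.normal(size=(4, 3))
        mean, var = posterior_predict(model, Xs)
        o_mean, o_var = dense_posterior(X, Y, Xs, p, noise)
        np.testing.assert_allclose(mean, o_mean, atol=1e-8)
        np.testing.assert_allclose(var[:, 0], o_var, atol=1e-8)

    def test_interpolation_limit(self, rng):
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 1))
        model = GPExpertModel(ARDKernelParams(1.0, np.ones(2)), 1e-10, X, Y)
        mean, var = posterior_predict(model, X)
        np.testing.assert_allclose(mean, Y, atol=1e-4)
        assert var.max() < 1e-4

    def test_prior_reversion_far_away(self, rng):
        X, Y = rng.normal(size=(6, 2)), rng.normal(size=(6, 1))
        model = GPExpertModel(ARDKernelParams(1.5, np.ones(2) * 0.5), 0.1, X, Y)
        mean, var = posterior_predict(model, np.full((1, 2), 100.0))
        assert abs(mean[0, 0]) < 1e-8
        assert var[0, 0] == pytest.approx(1.5, abs=1e-8)

    def test_posterior_variance_below_prior(self, rng):
        X, Y = rng.normal(size=(12, 3)), rng.normal(size=(12, 1))
        p = ARDKernelParams(2.0, rng.uniform(0.5, 2, 3))
        model = GPExpertModel(p, 0.1, X, Y)
        _, var = posterior_predict(model, rng.normal(size=(30, 3)))
        assert np.all(var <= 2.0 + 1e-10)

    def test_training_row_permutation_invariance(self, rng):
        X, Y = rng.normal(size=(9, 2)), rng.normal(size=(9, 2))
        p = ARDKernelParams(1.0, np.ones(2))
        perm = rng.permutation(9)
        Xs = rng.normal(size=(5, 2))
        m1, v1 = posterior_predict(GPExpertModel(p, 0.2, X, Y), Xs)
        m2, v2 = posterior_predict(GPExpertModel(p, 0.2, X[perm], Y[perm]), Xs)
        np.testing.assert_allclose(m1, m2, atol=1e-9)
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_extra_observation_never_increases_variance(self, rng):
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 1))
        p = ARDKernelParams(1.0, np.ones(2))
        Xs = rng.normal(size=(20, 2))
        _, v_small = posterior_predict(GPExpertModel(p, 0.1, X[:-1], Y[:-1]), Xs)
        _, v_full = posterior_predict(GPExpertModel(p, 0.1, X, Y), Xs)
        assert np.all(v_full <= v_small + 1e-9)


class TestFit:
    def test_zero_iterations_returns_init(self, rng):
        X, Y = rng.normal(size=(10, 2)), rng.normal(size=(10, 1))
        init = ARDKernelParams(1.5, np.array([0.8, 1.2]))
        model = fit_gp_expert(X, Y, init=init, noise_init=0.3, max_iter=0)
        assert model.kernel.variance == 1.5
        np.testing.assert_array_equal(model.kernel.lengthscales, [0.8, 1.2])
        assert model.noise_variance == 0.3

    def test_fit_never_worse_than_init(self, rng):
        X = rng.normal(size=(30, 3))
        Y = np.sin(X[:, :1]) + 0.1 * rng.normal(size=(30, 1))
        init = ARDKernelParams(1.0, np.ones(3))
        m0 = fit_gp_expert(X, Y, init=init, max_iter=0)
        m1 = fit_gp_expert(X, Y, init=init, max_iter=100)
        assert nlml(m1) <= nlml(m0) + 1e-9

    def test_lengthscale_ordering_recovery(self):
        # function varies fast along dim 0 (l=0.5), slowly along dim 1 (l=5)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-2, 2, size=(120, 2))
            true = ARDKernelParams(1.0, np.array([0.5, 5.0]))
            K = kernel_matrix(X, None, true, jitter=1e-8)
            f = np.linalg.cholesky(K) @ rng.normal(size=(120, 2))
            Y = f + 0.1 * rng.normal(size=f.shape)
            model = fit_gp_expert(X, Y)
            l1, l2 = model.kernel.lengthscales
            hits += l1 < l2
        assert hits >= 4

    def test_irrelevant_column_gets_larger_lengthscale(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        Y = np.sin(1.5 * X[:, :1]) + X[:, 1:2] + 0.1 * rng.normal(size=(100, 1))
        model = fit_gp_expert(X, Y)  # dim 2 is pure noise input
        ls = model.kernel.lengthscales
        assert ls[2] > ls[0] and ls[2] > ls[1]

    def test_constant_zero_target_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        Y = np.zeros((10, 2))
        Y[:, 0] = rng.normal(size=10)
        with pytest.raises(ValueError, match="constant-zero"):
            fit_gp_expert(X, Y)

    def test_adam_optimizer_path(self, rng):
        X = rng.normal(size=(20, 2))
        Y = np.sin(X[:, :1]) + 0.1 * rng.normal(size=(20, 1))
        init = ARDKernelParams(1.0, np.ones(2))
        m = fit_gp_expert(X, Y, init=init, optimizer="adam", max_iter=50)
        assert nlml(m) <= nlml(fit_gp_expert(X, Y, init=init, max_iter=0)) + 1e-9

    def test_subset_of_data_fallback(self, rng):
        X, Y = rng.normal(size=(50, 2)), rng.normal(size=(50, 1))
        m = fit_gp_expert(X, Y, max_iter=5, max_train=20, seed=3)
        assert m.n_train == 20


def test_save_load_roundtrip(tmp_path, rng):
    X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
    model = fit_gp_expert(X, Y, max_iter=10, label="ctrl")
    save_expert(model, tmp_path / "expert.npz")
    loaded = load_expert(tmp_path / "expert.npz")
    assert loaded.label == "ctrl"
    Xs = rng.normal(size=(3, 2))
    np.testing.assert_allclose(
        posterior_predict(model, Xs)[0], posterior_predict(loaded, Xs)[0], atol=1e-12
    )
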