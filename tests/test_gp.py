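"""Kriging core: correlation rule, concentrated likelihood, fit, prediction.

The reference implementation for the oracle checks is deliberately naive
dense linear algebra (explicit inverses), independent of the Cholesky code
path used by the package.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshlift.gp import (
    concentrated_nll,
    correlation,
    fit,
    load_model,
    predict,
    save_model,
    surrogate_from_theta,
)


def naive_profile(X, y, theta, nugget=1e-10):
    """Dense-inverse ordinary-kriging reference (oracle)."""
    l = len(y)
    R = correlation(X, X, theta) + nugget * np.eye(l)
    Ri = np.linalg.inv(R)
    one = np.ones(l)
    beta = one @ Ri @ y / (one @ Ri @ one)
    sigma2 = (y - beta) @ Ri @ (y - beta) / l
    nll = 0.5 * l * np.log(sigma2) + 0.5 * np.log(np.linalg.det(R))
    return R, Ri, beta, sigma2, nll


class TestCorrelation:
    def test_identical_points(self):
        x = np.array([[0.3, 0.7]])
        assert correlation(x, x, np.array([2.0, 3.0]))[0, 0] == 1.0

    def test_zero_theta_gives_unit_correlation(self):
        X = np.random.default_rng(0).uniform(size=(6, 4))
        assert np.all(correlation(X, X, np.zeros(4)) == 1.0)

    def test_closed_form_single_dimension(self):
        a, b = np.array([[0.0]]), np.array([[1.0]])
        assert correlation(a, b, np.array([1.0]))[0, 0] == pytest.approx(np.exp(-1.0))

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.zeros((2, 1)), np.zeros((2, 1)), np.array([-1.0]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.zeros((2, 2)), np.zeros((2, 3)), np.array([1.0, 1.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_values_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        theta = rng.uniform(0, 5, size=3)
        R = correlation(X, X, theta)
        assert np.all(R > 0) and np.all(R <= 1.0)
        assert np.allclose(np.diag(R), 1.0)


class TestConcentratedLikelihood:
    def test_matches_naive_dense_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            X = rng.uniform(size=(20, 3))
            y = rng.normal(size=20)
            theta = rng.uniform(0.1, 5.0, size=3)
            _, _, _, _, nll_ref = naive_profile(X, y, theta)
            assert concentrated_nll(theta, X, y) == pytest.approx(nll_ref, abs=1e-8)

    def test_two_sample_closed_form(self):
        """l=2, q=1: beta_hat = (y1+y2)/2 and sigma2_hat = ((y1-y2)/2)^2/(1-r)."""
        X = np.array([[0.0], [1.0]])
        y = np.array([3.0, 7.0])
        theta = np.array([0.8])
        r = np.exp(-0.8)
        model = surrogate_from_theta(X, y, theta)
        assert model.beta == pytest.approx(5.0, rel=1e-9)
        assert model.sigma2 == pytest.approx(4.0 / (1.0 - r), rel=1e-8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(15, 2))
        y = rng.normal(size=15)
        theta = np.array([1.0, 2.0])
        a = concentrated_nll(theta, X, y)
        b = concentrated_nll(theta, X, y + 123.456)
        assert a == pytest.approx(b, abs=1e-7)


class TestFit:
    def test_constant_target_degenerate_branch(self):
        X = np.random.default_rng(0).uniform(size=(10, 2))
        model, res = fit(X, np.full(10, 4.2), mode="isotropic", budget=10)
        assert res.degenerate and model.sigma2 == 0.0
        mu, var = predict(model, X)
        assert np.all(mu == 4.2) and np.all(var == 0.0)

    def test_isotropic_nested_in_anisotropic(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(30, 2))
        K = 1.5 * correlation(X, X, np.array([8.0, 0.2]))
        y = np.linalg.cholesky(K + 1e-10 * np.eye(30)) @ rng.normal(size=30)
        _, iso = fit(X, y, mode="isotropic", budget=400)
        _, aniso = fit(X, y, mode="anisotropic", budget=400)
        assert iso.theta_hat.size == 1 and aniso.theta_hat.size == 2
        assert iso.nll >= aniso.nll - 1e-8

    def test_iid_noise_pushes_theta_up(self):
        """Uncorrelated targets drive the correlation toward zero (large theta)."""
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(40, 2))
        y = rng.normal(size=40)
        _, res = fit(X, y, mode="isotropic", budget=400)
        assert res.theta_hat[0] >= 1e2

    def test_budget_validation(self):
        X = np.random.default_rng(0).uniform(size=(5, 1))
        with pytest.raises(ValueError):
            fit(X, np.arange(5.0), budget=0)

    def test_smooth_interpolation_of_quadratic(self):
        """With p=2 and small theta the mean interpolant reproduces a
        quadratic through 5 points to <1% between the points."""
        x = np.linspace(0, 1, 5)[:, None]
        y = 2.0 * x.ravel() ** 2 - x.ravel() + 0.5
        model = surrogate_from_theta(x, y, np.array([0.1]))
        xs = np.linspace(0, 1, 41)[:, None]
        mu = predict(model, xs, return_var=False)
        exact = 2.0 * xs.ravel() ** 2 - xs.ravel() + 0.5
        assert np.max(np.abs(mu - exact)) < 0.01 * np.max(np.abs(exact))


class TestPredict:
    def test_interpolates_training_data(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(20, 3))
        y = rng.normal(size=20)
        model, _ = fit(X, y, mode="anisotropic", budget=300)
        mu, var = predict(model, X)
        assert np.max(np.abs(mu - y)) < 1e-8
        assert np.max(var) < 1e-8 * model.sigma2

    def test_matches_naive_dense_implementation(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(20, 3))
        y = rng.normal(size=20)
        theta = np.array([2.0, 0.5, 1.0])
        model = surrogate_from_theta(X, y, theta)
        Xn = rng.uniform(size=(8, 3))
        mu, var = predict(model, Xn)
        R, Ri, beta, sigma2, _ = naive_profile(X, y, theta, nugget=model.nugget)
        one = np.ones(20)
        r = correlation(Xn, X, theta)
        mu_ref = beta + r @ Ri @ (y - beta)
        var_ref = sigma2 * (
            1.0 - np.einsum("ml,lk,mk->m", r, Ri, r)
            + (1.0 - r @ Ri @ one) ** 2 / (one @ Ri @ one)
        )
        assert np.allclose(mu, mu_ref, atol=1e-8)
        assert np.allclose(var, var_ref, atol=1e-8)

    def test_far_point_reverts_to_trend(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(12, 2))
        y = rng.normal(size=12)
        model = surrogate_from_theta(X, y, np.array([5.0, 5.0]))
        far = np.array([[1e3, -1e3]])
        mu, var = predict(model, far)
        assert mu[0] == pytest.approx(model.beta, abs=1e-12)
        assert var[0] == pytest.approx(
            model.sigma2 * (1.0 + 1.0 / model.one_Rinv_one), rel=1e-10
        )

    def test_mean_linear_in_targets(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(15, 2))
        y1, y2 = rng.normal(size=15), rng.normal(size=15)
        theta = np.array([1.0, 2.0])
        Xn = rng.uniform(size=(6, 2))

        def mean_resid(y):
            # strip the trend contribution to expose the linear-in-y part
            m = surrogate_from_theta(X, y, theta)
            return predict(m, Xn, return_var=False)

        a, b = 2.0, -3.0
        lhs = mean_resid(a * y1 + b * y2)
        rhs = a * mean_resid(y1) + b * mean_resid(y2)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_extra_training_point_cannot_increase_variance(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(15, 2))
        y = rng.normal(size=15)
        theta = np.array([2.0, 2.0])
        Xn = rng.uniform(size=(10, 2))
        _, var_small = predict(surrogate_from_theta(X[:-1], y[:-1], theta), Xn)
        _, var_full = predict(surrogate_from_theta(X, y, theta), Xn)
        assert np.all(var_full <= var_small + 1e-10)

    def test_dimension_mismatch_rejected(self):
        model = surrogate_from_theta(
            np.random.default_rng(0).uniform(size=(5, 2)), np.arange(5.0), np.array([1.0, 1.0])
        )
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 4)))


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    X = rng.uniform(size=(15, 3))
    y = rng.normal(size=15)
    model, _ = fit(X, y, mode="isotropic", budget=100)
    path = str(tmp_path / "model.gp.h5")
    save_model(model, path)
    loaded = load_model(path)
    Xn = rng.uniform(size=(4, 3))
    mu0, var0 = predict(model, Xn)
    mu1, var1 = predict(loaded, Xn)
    assert np.array_equal(mu0, mu1) and np.array_equal(var0, var1)
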