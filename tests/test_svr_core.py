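"""Kernel, dual solver and prediction against independent oracles."""

import numpy as np
import pytest

import pkpdsvr.svr_core as sc
from pkpdsvr import (
    FeatureScaler,
    SVRModel,
    gram_matrix,
    rbf_kernel,
    sigma_to_gamma,
    train_svr,
)

from _oracles import gram_double_loop, rbf_elementwise, solve_dual_qp


def random_problem(rng):
    n = int(rng.integers(2, 9))
    k = int(rng.integers(1, 4))
    X = rng.normal(size=(n, k))
    y = rng.normal(size=n) * 2.0
    C = 10 ** rng.uniform(-0.5, 1.7)
    eps = 10 ** rng.uniform(-2, -0.5)
    sigma = 10 ** rng.uniform(-0.3, 0.7)
    return X, y, C, eps, sigma


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.5, -2.0, 3.0])
        assert rbf_kernel(x, x, sigma=0.37) == pytest.approx(1.0)

    def test_closed_form_at_characteristic_distance(self):
        # ‖x-y‖² = 2σ² → e⁻¹
        sigma = 1.3
        x = np.zeros(2)
        y = np.array([np.sqrt(2.0) * sigma, 0.0])
        assert rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_elementwise_oracle(self):
        x, y = np.array([1.0, 2.0]), np.array([2.0, 4.0])
        sigma = 9.858
        assert rbf_kernel(x, y, sigma) == pytest.approx(
            rbf_elementwise(x, y, sigma), abs=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 5))
            s = 10 ** rng.uniform(-1, 1)
            assert rbf_kernel(x, y, s) == pytest.approx(rbf_kernel(y, x, s), abs=0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [1.0], sigma=0.0)
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [1.0, 2.0], sigma=1.0)


class TestGramMatrix:
    def test_psd_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 4))
        K = gram_matrix(X, sigma=0.8)
        np.testing.assert_allclose(K, K.T, atol=0)
        np.testing.assert_allclose(np.diag(K), 1.0, atol=0)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_identical_rows_give_unit_similarity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        K = gram_matrix(X, sigma=2.0)
        assert K[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_matches_double_loop_on_scaled_fixture(self, mc):
        Z = FeatureScaler.fit(mc.concentrations).transform(mc.concentrations)
        K = gram_matrix(Z, sigma=42.244)
        np.testing.assert_allclose(K, gram_double_loop(Z, 42.244), atol=1e-12)


class TestTrainSvr:
    def test_constant_target_inside_tube(self):
        X = np.arange(8.0).reshape(-1, 1)
        model = train_svr(X, np.full(8, 5.0), penalty=10, sigma=1, epsilon=0.1)
        assert model.n_support == 0
        assert model.bias == pytest.approx(5.0)
        np.testing.assert_allclose(model.predict(X), 5.0)

    def test_toy_line_matches_qp_oracle(self, toy_line_model):
        model, X, y = toy_line_model
        K = gram_matrix(X, model.sigma)
        beta, g, _ = sc.fit_dual(K, y, 100.0, 0.01)
        _, obj_oracle = solve_dual_qp(K, y, 100.0, 0.01)
        assert sc.dual_objective(K, y, 0.01, beta) == pytest.approx(obj_oracle, abs=1e-6)

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X, y, C, eps, sigma = random_problem(rng)
            m = train_svr(X, y, penalty=C, sigma=sigma, epsilon=eps, scale=False)
            assert abs(m.dual_coefs.sum()) < 1e-8 * max(1, C)
            assert np.all(np.abs(m.dual_coefs) <= C * (1 + 1e-10))
            assert np.all(m.dual_coefs != 0)  # stored SVs are genuinely active

    def test_oracle_equivalence_random_problems(self):
        """Dual objective and predictions match a dense QP solve (N ≤ 8)."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            X, y, C, eps, sigma = random_problem(rng)
            K = gram_matrix(X, sigma)
            beta, g, b = sc.fit_dual(K, y, C, eps)
            beta_q, obj_q = solve_dual_qp(K, y, C, eps)
            assert sc.dual_objective(K, y, eps, beta) == pytest.approx(obj_q, abs=1e-6)
            g_q = K @ beta_q
            b_q = sc._solve_bias(beta_q, g_q, y, C, eps)
            np.testing.assert_allclose(g + b, g_q + b_q, atol=1e-6)

    def test_nonbound_points_sit_in_tube(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X, y, C, eps, sigma = random_problem(rng)
            m = train_svr(X, y, penalty=C, sigma=sigma, epsilon=eps, scale=False)
            pred = m.predict(X)
            resid = np.abs(pred - y)
            at_bound = np.zeros(len(y), dtype=bool)
            # map stored coefficients back to the rows they came from
            for sv, coef in zip(m.support_vectors, m.dual_coefs):
                i = int(np.argmin(np.sum((X - sv) ** 2, axis=1)))
                if abs(abs(coef) - C) < 1e-7 * max(1, C):
                    at_bound[i] = True
            assert np.all(resid[~at_bound] <= eps + 1e-6)

    def test_interpolation_limit(self):
        """c → large, ε → 0 drives training residuals to zero."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(5, 2))
            y = rng.normal(size=5)
            m = train_svr(X, y, penalty=1e6, sigma=1.0, epsilon=1e-6, scale=False)
            assert np.max(np.abs(m.predict(X) - y)) < 1e-3

    def test_scale_invariance_of_predictions(self):
        """Affine rescaling of raw features is absorbed by the refit scaler."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        Xq = rng.normal(size=(4, 3))
        m1 = train_svr(X, y, penalty=10, sigma=2, epsilon=0.05, scale=True)
        scale = np.array([100.0, 0.01, 3.0])
        shift = np.array([-5.0, 2.0, 0.0])
        m2 = train_svr(X * scale + shift, y, penalty=10, sigma=2, epsilon=0.05, scale=True)
        np.testing.assert_allclose(m1.predict(Xq), m2.predict(Xq * scale + shift), atol=1e-8)

    def test_degenerate_identical_rows_flagged(self):
        X = np.ones((4, 2))
        y = np.array([0.0, 1.0, 2.0, 3.0])
        m = train_svr(X, y, penalty=5, sigma=1, epsilon=0.1)
        assert m.degenerate
        pred = m.predict(np.ones((3, 2)))
        assert np.ptp(pred) == pytest.approx(0.0)  # constant output

    def test_matches_sklearn_reference(self, mc):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        y = mc.endpoint("TXB2")
        m = train_svr(mc.concentrations, y, penalty=92.721, sigma=42.244, epsilon=0.1)
        Z = m.scaler.transform(mc.concentrations)
        ref = sklearn_svm.SVR(
            C=92.721, gamma=sigma_to_gamma(42.244), epsilon=0.1, tol=1e-10
        ).fit(Z, y)
        np.testing.assert_allclose(m.predict(mc.concentrations), ref.predict(Z), atol=1e-4)

    def test_input_validation(self):
        X = np.ones((3, 1)) * np.arange(3)[:, None]
        with pytest.raises(ValueError):
            train_svr(X, [1.0, 2.0], penalty=1, sigma=1)
        with pytest.raises(ValueError):
            train_svr(X, [1, 2, np.nan], penalty=1, sigma=1)
        with pytest.raises(ValueError):
            train_svr(X, [1, 2, 3], penalty=-1, sigma=1)
        with pytest.raises(ValueError):
            train_svr(X, [1, 2, 3], penalty=1, sigma=1, epsilon=-0.1)


class TestPredict:
    def test_single_support_vector_at_itself(self):
        s = np.array([[0.3, -1.2]])
        m = SVRModel(
            support_vectors=s,
            dual_coefs=np.array([1.0]),
            bias=0.0,
            sigma=2.0,
            penalty=1.0,
            epsilon=0.1,
            scaler=FeatureScaler.identity(2),
        )
        assert m.predict(s)[0] == pytest.approx(1.0)

    def test_empty_expansion_returns_bias(self):
        m = SVRModel(
            support_vectors=np.empty((0, 2)),
            dual_coefs=np.empty(0),
            bias=-1.5,
            sigma=1.0,
            penalty=1.0,
            epsilon=0.1,
            scaler=FeatureScaler.identity(2),
        )
        np.testing.assert_allclose(m.predict(np.zeros((5, 2))), -1.5)

    def test_dimension_mismatch(self, toy_line_model):
        model, _, _ = toy_line_model
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 3)))

    def test_expansion_reproduces_oracle_training_predictions(self):
        rng = np.random.default_rng(21)
        X, y, C, eps, sigma = random_problem(rng)
        m = train_svr(X, y, penalty=C, sigma=sigma, epsilon=eps, scale=False)
        K = gram_matrix(X, sigma)
        beta_q, _ = solve_dual_qp(K, y, C, eps)
        g_q = K @ beta_q
        b_q = sc._solve_bias(beta_q, g_q, y, C, eps)
        np.testing.assert_allclose(m.predict(X), g_q + b_q, atol=1e-8)


class TestSerialization:
    def test_json_round_trip(self, mc, tmp_path):
        y = mc.endpoint("6_keto_PGF1a")
        m = train_svr(mc.concentrations, y, penalty=57.641, sigma=88.907)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = SVRModel.load(path)
        np.testing.assert_array_equal(m.dual_coefs, m2.dual_coefs)
        np.testing.assert_allclose(
            m.predict(mc.concentrations), m2.predict(mc.concentrations), atol=0
        )


def test_sigma_gamma_round_trip():
    assert sc.gamma_to_sigma(sigma_to_gamma(9.858)) == pytest.approx(9.858)
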