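"""Unit tests for the ELM layers, closed-form solvers and estimators."""

import numpy as np
import pytest
from scipy.stats import chisquare

from emoelm import (
    ELMAutoencoder,
    ELMClassifier,
    HiddenLayer,
    NonlinearRandomProjection,
    SparseELMAutoencoder,
    eigen_beta,
    hidden_output,
    linear_transform,
    make_orthogonal_layer,
    make_sparse_layer,
    pinv_beta,
    ridge_beta,
)


class TestOrthogonalLayer:
    def test_unit_vector_when_scalar(self):
        layer = make_orthogonal_layer(1, 1, seed=0)
        assert abs(abs(layer.W[0, 0]) - 1.0) < 1e-12
        assert abs(abs(layer.b[0]) - 1.0) < 1e-12

    @pytest.mark.parametrize("n,L", [(10, 4), (10, 10), (50, 1), (50, 50), (7, 3)])
    def test_gram_is_identity_and_unit_bias(self, n, L):
        layer = make_orthogonal_layer(n, L, seed=3)
        assert np.abs(layer.W.T @ layer.W - np.eye(L)).max() < 1e-8
        assert abs(layer.b @ layer.b - 1.0) < 1e-8

    def test_gram_identity_over_all_small_shapes(self):
        for n in range(1, 51, 7):
            for L in range(1, n + 1, 5):
                layer = make_orthogonal_layer(n, L, seed=n * 100 + L)
                assert np.abs(layer.W.T @ layer.W - np.eye(L)).max() < 1e-8

    def test_distinct_seeds_distinct_weights_same_gram(self):
        a = make_orthogonal_layer(10, 4, seed=0)
        b = make_orthogonal_layer(10, 4, seed=1)
        assert not np.allclose(a.W, b.W)
        assert np.allclose(a.W.T @ a.W, b.W.T @ b.W, atol=1e-8)

    def test_deterministic_for_fixed_seed(self):
        a = make_orthogonal_layer(10, 4, seed=5)
        b = make_orthogonal_layer(10, 4, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)

    def test_rejects_wide_layer(self):
        with pytest.raises(ValueError, match="L <= n"):
            make_orthogonal_layer(3, 4, seed=0)


class TestSparseLayer:
    def test_three_values_with_unit_magnitude_at_L3(self):
        layer = make_sparse_layer(40, 3, seed=0)
        assert set(np.unique(layer.W)) <= {-1.0, 0.0, 1.0}

    def test_entry_distribution_matches_achlioptas_probabilities(self):
        layer = make_sparse_layer(200, 100, seed=1)
        s = np.sqrt(3.0 / 100)
        W = layer.W
        n_entries = W.size
        zero_frac = np.mean(W == 0)
        assert abs(zero_frac - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / n_entries)
        plus, minus = np.mean(W == s), np.mean(W == -s)
        tol = 4 * np.sqrt((1 / 6) * (5 / 6) / n_entries)
        assert abs(plus - 1 / 6) < tol
        assert abs(minus - 1 / 6) < tol
        assert abs(plus - minus) < 2 * tol

    def test_chi_square_goodness_of_fit(self):
        layer = make_sparse_layer(200, 100, seed=2)
        s = np.sqrt(3.0 / 100)
        obs = [np.sum(layer.W == s), np.sum(layer.W == 0), np.sum(layer.W == -s)]
        n = layer.W.size
        _, p = chisquare(obs, f_exp=[n / 6, 2 * n / 3, n / 6])
        assert p > 0.01

    def test_bias_uses_same_alphabet(self):
        layer = make_sparse_layer(50, 4, seed=3)
        s = np.sqrt(3.0 / 4)
        assert set(np.unique(layer.b)) <= {-s, 0.0, s}


class TestHiddenOutput:
    def test_sigmoid_of_zero_is_half(self):
        layer = HiddenLayer(np.ones((3, 2)), np.zeros(2))
        H = hidden_output(np.zeros((4, 3)), layer)
        np.testing.assert_allclose(H, 0.5)

    def test_scalar_sigmoid_value(self):
        # sigmoid(ln 3) = 3/4
        layer = HiddenLayer(np.array([[1.0]]), np.array([0.0]))
        H = hidden_output(np.array([[np.log(3.0)]]), layer)
        assert abs(H[0, 0] - 0.75) < 1e-12

    def test_entries_strictly_in_unit_interval(self, rng):
        layer = HiddenLayer(rng.normal(size=(6, 4)), rng.normal(size=4))
        # scale kept moderate: float64 sigmoid saturates to exactly 0/1
        # beyond |z| ~ 37, where the open-interval property only holds in
        # exact arithmetic
        H = hidden_output(rng.normal(scale=3, size=(50, 6)), layer)
        assert np.all(H > 0) and np.all(H < 1)

    def test_shape_mismatch_raises(self, rng):
        layer = HiddenLayer(rng.normal(size=(6, 4)), rng.normal(size=4))
        with pytest.raises(ValueError, match="features"):
            hidden_output(rng.normal(size=(5, 7)), layer)


class TestPinvBeta:
    def test_identity_design_returns_target(self, rng):
        X = rng.random((6, 6))
        np.testing.assert_allclose(pinv_beta(np.eye(6), X), X, atol=1e-12)

    def test_orthonormal_columns_closed_form(self, rng):
        H, _ = np.linalg.qr(rng.normal(size=(20, 5)))
        X = rng.random((20, 8))
        np.testing.assert_allclose(pinv_beta(H, X), H.T @ X, atol=1e-10)

    def test_normal_equation_residual_orthogonality(self, rng):
        H = rng.normal(size=(20, 5))
        X = rng.random((20, 8))
        beta = pinv_beta(H, X)
        scale = np.abs(H.T @ X).max()
        assert np.abs(H.T @ (H @ beta - X)).max() < 1e-6 * scale
        # independent least-squares oracle via the pseudoinverse
        np.testing.assert_allclose(beta, np.linalg.pinv(H) @ X, atol=1e-8)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pinv_beta(np.empty((0, 3)), np.empty((0, 2)))


class TestRidgeBeta:
    def test_small_and_large_sample_forms_agree(self, rng):
        H = rng.normal(size=(30, 6))
        T = rng.normal(size=(30, 4))
        b_small = ridge_beta(H, T, lam=10.0, mode="small-sample")
        b_large = ridge_beta(H, T, lam=10.0, mode="large-sample")
        assert np.abs(b_small - b_large).max() < 1e-6

    def test_huge_lambda_approaches_pseudoinverse(self, rng):
        H = rng.normal(size=(30, 6))
        T = rng.normal(size=(30, 4))
        np.testing.assert_allclose(
            ridge_beta(H, T, lam=1e12, mode="large-sample"),
            pinv_beta(H, T),
            atol=1e-6,
        )

    def test_zero_target_gives_zero_weights(self, rng):
        H = rng.normal(size=(10, 3))
        assert np.abs(ridge_beta(H, np.zeros((10, 2)), lam=1.0)).max() == 0

    def test_auto_mode_picks_small_system(self, rng):
        H = rng.normal(size=(4, 10))
        T = rng.normal(size=(4, 2))
        np.testing.assert_allclose(
            ridge_beta(H, T, lam=5.0, mode="auto"),
            ridge_beta(H, T, lam=5.0, mode="small-sample"),
        )


class TestEigenBeta:
    def test_full_eigenbasis_degenerates_to_WT(self, rng):
        # with V spanning all of R^n, V V^T = I and beta = W^T
        X = rng.random((20, 4))
        layer = make_orthogonal_layer(4, 4, seed=0)
        np.testing.assert_allclose(eigen_beta(X, layer), layer.W.T, atol=1e-10)

    def test_rank_one_data_uses_principal_eigenvector(self, rng):
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        X = np.outer(rng.normal(size=15), v)  # rank-1
        layer = make_orthogonal_layer(6, 1, seed=1)
        expected = layer.W.T @ np.outer(v, v)
        got = eigen_beta(X, layer)
        # eigenvector sign is arbitrary but v v^T is not
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_projection_rank_bound(self, rng):
        X = rng.random((25, 8))
        layer = make_orthogonal_layer(8, 3, seed=2)
        feats = linear_transform(X, eigen_beta(X, layer))
        assert np.linalg.matrix_rank(feats) <= 3

    def test_eigendecomposition_oracle(self, rng):
        X = rng.random((30, 5))
        layer = make_sparse_layer(5, 3, seed=4)
        evals, evecs = np.linalg.eigh(X.T @ X)
        V = evecs[:, np.argsort(evals)[::-1][:3]]
        np.testing.assert_allclose(eigen_beta(X, layer), layer.W.T @ V @ V.T, atol=1e-8)


class TestLinearTransform:
    def test_selector_beta_picks_columns(self, rng):
        X = rng.random((5, 4))
        beta = np.hstack([np.eye(2), np.zeros((2, 2))])
        np.testing.assert_allclose(linear_transform(X, beta), X[:, :2])

    def test_matches_explicit_dot_products(self, rng):
        X = rng.random((5, 4))
        beta = rng.normal(size=(2, 4))
        expected = np.array([[row @ brow for brow in beta] for row in X])
        np.testing.assert_allclose(linear_transform(X, beta), expected, atol=1e-12)


class TestELMClassifier:
    def test_separable_toy_training_accuracy_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(3, 0.1, (20, 3))])
        y = np.repeat([1, 2], 20)
        clf = ELMClassifier(n_hidden=50, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_fixed_seed_identical_predictions(self, rng):
        X = rng.random((40, 4))
        y = rng.integers(1, 4, size=40)
        p1 = ELMClassifier(n_hidden=30, random_state=7).fit(X, y).predict(X)
        p2 = ELMClassifier(n_hidden=30, random_state=7).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_label_code_permutation_permutes_beta_columns(self, rng):
        X = rng.random((30, 4))
        y = rng.integers(0, 3, size=30)
        a = ELMClassifier(n_hidden=20, random_state=1).fit(X, y)
        b = ELMClassifier(n_hidden=20, random_state=1).fit(X, 2 - y)
        np.testing.assert_allclose(a.beta_, b.beta_[:, ::-1], atol=1e-10)
        np.testing.assert_array_equal(a.predict(X), 2 - b.predict(X))

    def test_single_class_degenerates_gracefully(self, rng):
        X = rng.random((10, 3))
        clf = ELMClassifier(n_hidden=10, random_state=0).fit(X, np.ones(10))
        assert (clf.predict(X) == 1).all()


class TestLinearAutoencoders:
    @pytest.mark.parametrize("cls", [ELMAutoencoder, SparseELMAutoencoder])
    def test_fit_transform_shape_and_determinism(self, cls, rng):
        X = rng.random((30, 8))
        F1 = cls(n_components=3, random_state=0).fit_transform(X)
        F2 = cls(n_components=3, random_state=0).fit_transform(X)
        assert F1.shape == (30, 3)
        np.testing.assert_array_equal(F1, F2)

    def test_nrp_outputs_sigmoid_range(self, rng):
        X = rng.random((30, 8))
        F = NonlinearRandomProjection(n_components=4, random_state=0).fit_transform(X)
        assert F.shape == (30, 4)
        assert np.all((F > 0) & (F < 1))
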