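"""Extreme learning machine building blocks.

An ELM is a single-hidden-layer network whose hidden weights are *not*
trained: they are drawn at random (here either dense-orthogonal or sparse
three-valued) and only the output weights ``beta`` are solved in closed
form, by a Moore-Penrose pseudoinverse or by ridge regression.  The
autoencoder variants (ELM-AE / SELM-AE) reconstruct the input through the
random hidden map and then use ``beta`` itself as a *linear* feature
projection ``X @ beta.T``.

This module holds the random hidden layers, the closed-form solvers, and
scikit-learn estimators wrapping them: :class:`ELMClassifier`,
:class:`ELMAutoencoder`, :class:`SparseELMAutoencoder` and the
unoptimized :class:`NonlinearRandomProjection` baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "HiddenLayer",
    "make_orthogonal_layer",
    "make_sparse_layer",
    "hidden_output",
    "pinv_beta",
    "ridge_beta",
    "eigen_beta",
    "linear_transform",
    "ELMClassifier",
    "ELMAutoencoder",
    "SparseELMAutoencoder",
    "NonlinearRandomProjection",
]

_ACTIVATIONS = {"sigmoid": expit}


@dataclass(frozen=True)
class HiddenLayer:
    """Random hidden layer: weights ``W`` (n x L), bias ``b`` (L,).

    ``variant`` records how the layer was constructed: ``"orthogonal"``
    (W^T W = I, b^T b = 1), ``"sparse"`` (three-valued entries
    +/-sqrt(3/L) and 0), or ``"free"`` (arbitrary, e.g. decoded from an
    evolved decision vector).
    """

    W: np.ndarray
    b: np.ndarray
    activation: str = "sigmoid"
    variant: str = "free"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if W.ndim != 2 or b.ndim != 1 or W.shape[1] != b.shape[0]:
            raise ValueError(
                f"inconsistent layer shapes: W {W.shape}, b {b.shape}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


def make_orthogonal_layer(n: int, L: int, seed=None) -> HiddenLayer:
    """Draw an orthogonal hidden layer: W^T W = I_L, b^T b = 1.

    W is the reduced-QR orthonormalization of a standard-normal n x L
    draw; b is a standard-normal vector scaled to unit norm.  Requires
    L <= n (more orthonormal columns than rows cannot exist).
    """
    if not 1 <= L <= n:
        raise ValueError(
            f"orthogonal layer needs 1 <= L <= n, got L={L}, n={n}"
        )
    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((n, L)))
    b = rng.standard_normal(L)
    b /= np.linalg.norm(b)
    return HiddenLayer(W, b, variant="orthogonal")


def make_sparse_layer(n: int, L: int, seed=None) -> HiddenLayer:
    """Draw a sparse three-valued hidden layer.

    Every entry of W and b is independently +sqrt(3/L) with probability
    1/6, 0 with probability 2/3, and -sqrt(3/L) with probability 1/6 —
    the sparse random projection of Achlioptas, scaled by the hidden
    width.
    """
    if n < 1 or L < 1:
        raise ValueError(f"need n >= 1 and L >= 1, got n={n}, L={L}")
    rng = np.random.default_rng(seed)
    s = np.sqrt(3.0 / L)
    vals = np.array([s, 0.0, -s])
    draw = rng.choice(3, size=(n + 1, L), p=[1 / 6, 2 / 3, 1 / 6])
    M = vals[draw]
    return HiddenLayer(M[:n], M[n], variant="sparse")


def hidden_output(X: np.ndarray, layer: HiddenLayer) -> np.ndarray:
    """Hidden activations H[i, j] = g(<w_j, x_i> + b_j), shape N x L."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != layer.n_features:
        raise ValueError(
            f"X has shape {X.shape}, layer expects {layer.n_features} features"
        )
    g = _ACTIVATIONS[layer.activation]
    return g(X @ layer.W + layer.b)


def pinv_beta(H: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights ``beta = pinv(H) @ X``.

    Solves min_beta ||H beta - X||_F via SVD-based least squares; the
    residual is orthogonal to the column space of H (normal equations).
    """
    H = np.asarray(H, dtype=float)
    X = np.asarray(X, dtype=float)
    if H.size == 0 or X.size == 0:
        raise ValueError("empty input to pinv_beta")
    if H.shape[0] != X.shape[0]:
        raise ValueError(f"row mismatch: H {H.shape} vs X {X.shape}")
    beta, *_ = np.linalg.lstsq(H, X, rcond=None)
    return beta


def ridge_beta(
    H: np.ndarray,
    T: np.ndarray,
    lam: float = 1e6,
    mode: str = "auto",
) -> np.ndarray:
    """Ridge-regularized output weights.

    mode="small-sample" uses beta = H^T (H H^T + I/lam)^(-1) T (an N x N
    solve, cheap when there are fewer samples than hidden neurons);
    mode="large-sample" uses beta = (H^T H + I/lam)^(-1) H^T T (an L x L
    solve).  The two are algebraically identical; "auto" picks the
    smaller system (small-sample iff N <= L).
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if H.shape[0] != T.shape[0]:
        raise ValueError(f"row mismatch: H {H.shape} vs T {T.shape}")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    N, L = H.shape
    if mode == "auto":
        mode = "small-sample" if N <= L else "large-sample"
    if mode == "small-sample":
        G = H @ H.T
        G.flat[:: N + 1] += 1.0 / lam
        return H.T @ np.linalg.solve(G, T)
    if mode == "large-sample":
        G = H.T @ H
        G.flat[:: L + 1] += 1.0 / lam
        return np.linalg.solve(G, H.T @ T)
    raise ValueError(f"unknown mode {mode!r}")


def eigen_beta(X: np.ndarray, layer: HiddenLayer) -> np.ndarray:
    """Autoencoder output weights beta = W^T V V^T.

    V holds the top-L eigenvectors (descending eigenvalue) of the raw,
    uncentered Gram matrix X^T X.  Used by the linear ELM-AE / SELM-AE
    feature extractors, where the feature map becomes
    ``X @ beta.T = X V V^T W``.
    """
    X = np.asarray(X, dtype=float)
    n, L = layer.n_features, layer.n_hidden
    if X.ndim != 2 or X.shape[1] != n:
        raise ValueError(f"X has shape {X.shape}, layer expects {n} features")
    if L > n:
        raise ValueError(f"eigen_beta needs L <= n, got L={L}, n={n}")
    evals, evecs = np.linalg.eigh(X.T @ X)
    V = evecs[:, ::-1][:, :L]  # top-L, descending eigenvalue
    return layer.W.T @ V @ V.T


def linear_transform(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Linear feature projection X @ beta.T (N x L)."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[1]:
        raise ValueError(f"shape mismatch: X {X.shape}, beta {beta.shape}")
    return X @ beta.T


def _uniform_layer(n: int, L: int, low: float, high: float, rng) -> HiddenLayer:
    W = rng.uniform(low, high, size=(n, L))
    b = rng.uniform(low, high, size=L)
    return HiddenLayer(W, b, variant="free")


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Basic ELM classifier with a random sigmoid hidden layer.

    Hidden weights and biases are drawn uniform in ``weight_range`` and
    never trained; output weights are solved by ridge regression against
    one-hot class targets.  Prediction is the argmax of ``h(x) @ beta``.

    Parameters
    ----------
    n_hidden : hidden-neuron count (default 500, the standard choice for
        hyperspectral pixel classification benchmarks).
    lam : ridge regularization coefficient lambda; the penalty enters as
        I/lambda, so larger lambda means *less* regularization.
    ridge_mode : "auto" | "small-sample" | "large-sample".
    """

    def __init__(
        self,
        n_hidden: int = 500,
        lam: float = 1e6,
        ridge_mode: str = "auto",
        weight_range: tuple = (-1.0, 1.0),
        random_state=None,
    ):
        self.n_hidden = n_hidden
        self.lam = lam
        self.ridge_mode = ridge_mode
        self.weight_range = weight_range
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        lo, hi = self.weight_range
        self.layer_ = _uniform_layer(X.shape[1], self.n_hidden, lo, hi, rng)
        T = np.zeros((X.shape[0], len(self.classes_)))
        T[np.arange(X.shape[0]), y_idx] = 1.0
        H = hidden_output(X, self.layer_)
        self.beta_ = ridge_beta(H, T, lam=self.lam, mode=self.ridge_mode)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X)
        return hidden_output(X, self.layer_) @ self.beta_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


class _LinearELMAE(TransformerMixin, BaseEstimator):
    """Shared fit/transform for the linear autoencoder variants."""

    _variant = "orthogonal"

    def __init__(self, n_components: int = 10, random_state=None):
        self.n_components = n_components
        self.random_state = random_state

    def _make_layer(self, n):
        if self._variant == "orthogonal":
            return make_orthogonal_layer(n, self.n_components, self.random_state)
        return make_sparse_layer(n, self.n_components, self.random_state)

    def fit(self, X, y=None):
        X = check_array(X)
        self.layer_ = self._make_layer(X.shape[1])
        self.beta_ = eigen_beta(X, self.layer_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X)
        return linear_transform(X, self.beta_)


class ELMAutoencoder(_LinearELMAE):
    """Linear ELM autoencoder (orthogonal random hidden layer).

    Features are the linear projection ``X @ beta.T`` with
    ``beta = W^T V V^T`` built from the top-``n_components`` eigenvectors
    of X^T X.  Requires ``n_components <= n_features``.
    """

    _variant = "orthogonal"


class SparseELMAutoencoder(_LinearELMAE):
    """Linear sparse ELM autoencoder (three-valued random hidden layer)."""

    _variant = "sparse"


class NonlinearRandomProjection(TransformerMixin, BaseEstimator):
    """Unoptimized nonlinear random projection g(XW + b).

    The plain ELM hidden map with uniform random weights — the baseline
    that evolutionary optimization of (W, b) is measured against.
    """

    def __init__(
        self,
        n_components: int = 10,
        weight_range: tuple = (-1.0, 1.0),
        random_state=None,
    ):
        self.n_components = n_components
        self.weight_range = weight_range
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        rng = np.random.default_rng(self.random_state)
        lo, hi = self.weight_range
        self.layer_ = _uniform_layer(X.shape[1], self.n_components, lo, hi, rng)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "layer_")
        X = check_array(X)
        return hidden_output(X, self.layer_)
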