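"""The two conflicting objectives driving the evolved autoencoder.

A candidate encoder is a flat decision vector
``alpha = [w11, ..., w1L, ..., wn1, ..., wnL, b1, ..., bL]`` holding all
hidden weights and biases.  It is scored by

* ``f1`` — activation sparsity: the summed KL divergence between a small
  target activation ``rho`` (default 0.05) and each hidden neuron's mean
  sigmoid activation over the data.  Driving mean activations to
  ``rho`` forces most neurons to be nearly silent for most samples.
* ``f2`` — reconstruction fidelity: K-fold cross-validated RMSE of the
  linear decoder fitted on the hidden outputs.  Per fold, output weights
  are solved by pseudoinverse on the training folds and the held-out
  fold is reconstructed; ``f2`` is the mean of the per-fold RMSEs.

The two conflict: a silent hidden layer carries little information, so a
sparser code reconstructs worse.  Both are pure functions of
``(alpha, X, fold seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elm import HiddenLayer, hidden_output, pinv_beta

__all__ = [
    "CVSetting",
    "decode",
    "encode",
    "mean_activation",
    "kl_sparsity",
    "fold_indices",
    "cv_rmse",
    "evaluate",
    "ObjectiveEvaluator",
]

#: clip mean activations into [EPS, 1-EPS] before taking logs
EPS = 1e-6


@dataclass(frozen=True)
class CVSetting:
    """K-fold assignment for the reconstruction objective.

    Folds are contiguous blocks of one fixed random permutation drawn
    from ``seed``, so every candidate in an evolutionary run is scored
    on the same partition.
    """

    n_folds: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError(f"need at least 2 folds, got {self.n_folds}")


def decode(alpha: np.ndarray, n: int, L: int) -> HiddenLayer:
    """Unflatten a decision vector into a hidden layer.

    The layout is row-major over input index then hidden index —
    ``alpha[(i-1)*L + j]`` is W[i, j] — with the L biases trailing.
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != n * L + L:
        raise ValueError(
            f"decision vector has length {alpha.size}, expected n*L+L={n * L + L}"
        )
    W = alpha[: n * L].reshape(n, L)
    b = alpha[n * L :]
    return HiddenLayer(W, b, variant="free")


def encode(layer: HiddenLayer) -> np.ndarray:
    """Flatten a hidden layer into a decision vector (inverse of decode)."""
    return np.concatenate([layer.W.ravel(), layer.b])


def mean_activation(H: np.ndarray) -> np.ndarray:
    """Per-neuron mean activation rho_hat_j = mean_i H[i, j]."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError(f"H must be a nonempty 2-D matrix, got shape {H.shape}")
    return H.mean(axis=0)


def kl_sparsity(rho_hat: np.ndarray, rho: float = 0.05) -> float:
    """Summed Bernoulli KL divergence sum_j KL(rho || rho_hat_j).

    KL(rho || q) = rho ln(rho/q) + (1-rho) ln((1-rho)/(1-q)); natural
    log.  Nonnegative, zero iff every rho_hat_j equals rho.  Activations
    are clipped to [EPS, 1-EPS] so saturated neurons stay finite.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    q = np.clip(np.asarray(rho_hat, dtype=float), EPS, 1.0 - EPS)
    return float(
        np.sum(rho * np.log(rho / q) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - q)))
    )


def fold_indices(N: int, cv: CVSetting) -> list[np.ndarray]:
    """Disjoint validation-fold index arrays covering range(N)."""
    if cv.n_folds > N:
        raise ValueError(f"cannot make {cv.n_folds} folds from {N} samples")
    perm = np.random.default_rng(cv.seed).permutation(N)
    folds = np.array_split(perm, cv.n_folds)
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"{cv.n_folds} folds leave an empty validation fold")
    return folds


def _cv_rmse_from_H(X: np.ndarray, H: np.ndarray, folds) -> float:
    """Mean per-fold reconstruction RMSE given precomputed activations.

    The hidden map is row-wise, so training/validation activations are
    slices of the full H.
    """
    N, n = X.shape
    mask = np.ones(N, dtype=bool)
    rmses = []
    for val in folds:
        mask[:] = True
        mask[val] = False
        beta = pinv_beta(H[mask], X[mask])
        resid = X[val] - H[val] @ beta
        rmses.append(np.sqrt(np.sum(resid**2) / (len(val) * n)))
    return float(np.mean(rmses))


def cv_rmse(X: np.ndarray, alpha: np.ndarray, cv: CVSetting) -> float:
    """K-fold cross-validated reconstruction RMSE of a candidate encoder.

    ``alpha`` must decode against X's feature count; the hidden width is
    inferred from the vector length (L = len(alpha) / (n + 1)).
    """
    X = np.asarray(X, dtype=float)
    N, n = X.shape
    L, rem = divmod(np.asarray(alpha).size, n + 1)
    if rem:
        raise ValueError(
            f"decision vector of length {np.asarray(alpha).size} does not "
            f"match {n} features"
        )
    layer = decode(alpha, n, L)
    H = hidden_output(X, layer)
    return _cv_rmse_from_H(X, H, fold_indices(N, cv))


def evaluate(
    alpha: np.ndarray,
    X: np.ndarray,
    rho: float = 0.05,
    cv: CVSetting = CVSetting(),
) -> tuple[float, float]:
    """Score one candidate: (f1 KL sparsity, f2 CV reconstruction RMSE).

    f1 uses the hidden output over the *full* data; f2 uses held-out
    folds only.
    """
    return ObjectiveEvaluator(X, rho=rho, cv=cv)(alpha)


class ObjectiveEvaluator:
    """Callable scoring engine reused across an evolutionary run.

    Fixes the data, the sparsity target and the fold partition once, so
    every candidate is evaluated under identical conditions and the pair
    (f1, f2) is a pure function of alpha.
    """

    def __init__(
        self,
        X: np.ndarray,
        L: int | None = None,
        rho: float = 0.05,
        cv: CVSetting = CVSetting(),
    ):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or not np.all(np.isfinite(self.X)):
            raise ValueError("X must be a finite 2-D sample matrix")
        self.n = self.X.shape[1]
        self.L = L
        self.rho = rho
        self.cv = cv
        self.folds = fold_indices(self.X.shape[0], cv)

    @property
    def n_variables(self) -> int:
        if self.L is None:
            raise ValueError("hidden width L not fixed for this evaluator")
        return self.n * self.L + self.L

    def __call__(self, alpha: np.ndarray) -> tuple[float, float]:
        alpha = np.asarray(alpha, dtype=float)
        L = self.L
        if L is None:
            L, rem = divmod(alpha.size, self.n + 1)
            if rem:
                raise ValueError("alpha length incompatible with feature count")
        layer = decode(alpha, self.n, L)
        H = hidden_output(self.X, layer)
        f1 = kl_sparsity(mean_activation(H), self.rho)
        f2 = _cv_rmse_from_H(self.X, H, self.folds)
        return f1, f2
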