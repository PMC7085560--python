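"""End-to-end evolved sparse feature learning and its evaluation harness.

:class:`EMOELM` is the headline estimator: it evolves the hidden layer
of an ELM autoencoder with NSGA-II against the sparsity/reconstruction
objective pair, picks one Pareto solution (min_f1, min_f2 or knee), and
exposes the selected encoder as a scikit-learn transformer
``X -> g(X W_F + b_F)``.

The module also carries the evaluation harness used to compare feature
extractors: the per-sample L2/L1 sparsity score, OA/AA/Kappa
classification metrics, and the repeated stratified-split protocol
(10% train, 500-hidden-neuron ELM classifier, mean +/- std over 10
repeats).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted

from . import knee as _knee
from .elm import ELMClassifier, hidden_output
from .nsga2 import EvolutionConfig, ParetoArchive, evolve
from .objectives import CVSetting, ObjectiveEvaluator, decode

__all__ = [
    "EMOELM",
    "l2l1_sparsity",
    "classification_metrics",
    "evaluate_features",
    "EvaluationReport",
]


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    # sklearn random_state and user-facing seeds must fit in int32
    return int(seed_seq.generate_state(1)[0] % (2**31))


class EMOELM(TransformerMixin, BaseEstimator):
    """Evolutionary multiobjective ELM autoencoder feature learner.

    The encoder's weights and biases form one flat decision vector that
    NSGA-II evolves within ``bounds`` against two minimized objectives:
    summed KL divergence between the target activation ``rho`` and each
    neuron's mean sigmoid activation (f1), and K-fold cross-validated
    reconstruction RMSE with a pseudoinverse linear decoder (f2).  One
    archive member is then selected by ``strategy`` and frozen as the
    encoder.

    Parameters
    ----------
    n_components : hidden width L (number of learned features).
    rho : target mean activation in (0, 1); small values drive a sparse
        code.  Default 0.05.
    cv : folds for the reconstruction objective (default 3).
    pop_size, n_gen : NSGA-II population and generation budget; the
        reference experimental setting is 50 x 5000, far more than small
        problems need — scale ``n_gen`` down for exploratory runs.
    strategy : "min_f1" | "min_f2" | "knee" Pareto selection.
    bounds : box constraint on every weight and bias.

    Attributes
    ----------
    W_, b_ : selected encoder parameters (n x L, L).
    alpha_ : the selected flat decision vector.
    f1_, f2_ : objectives of the selected solution.
    archive_ : the full final Pareto archive.
    selection_ : :class:`~emoelm.knee.SelectionResult` with diagnostics.
    """

    def __init__(
        self,
        n_components: int = 10,
        rho: float = 0.05,
        cv: int = 3,
        pop_size: int = 50,
        n_gen: int = 5000,
        crossover_prob: float = 0.9,
        crossover_eta: float = 15.0,
        mutation_prob: float | None = None,
        mutation_eta: float = 20.0,
        bounds: tuple = (-1.0, 1.0),
        strategy: str = "knee",
        random_state=None,
    ):
        self.n_components = n_components
        self.rho = rho
        self.cv = cv
        self.pop_size = pop_size
        self.n_gen = n_gen
        self.crossover_prob = crossover_prob
        self.crossover_eta = crossover_eta
        self.mutation_prob = mutation_prob
        self.mutation_eta = mutation_eta
        self.bounds = bounds
        self.strategy = strategy
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        ss = np.random.SeedSequence(self.random_state)
        ss_evo, ss_folds = ss.spawn(2)
        evaluator = ObjectiveEvaluator(
            X,
            L=self.n_components,
            rho=self.rho,
            cv=CVSetting(n_folds=self.cv, seed=_child_seed(ss_folds)),
        )
        config = EvolutionConfig(
            pop_size=self.pop_size,
            n_gen=self.n_gen,
            crossover_prob=self.crossover_prob,
            crossover_eta=self.crossover_eta,
            mutation_prob=self.mutation_prob,
            mutation_eta=self.mutation_eta,
            bounds=tuple(self.bounds),
            seed=_child_seed(ss_evo),
        )
        self.archive_ = evolve(evaluator, evaluator.n_variables, config)
        self.selection_ = _knee.select(self.archive_, strategy=self.strategy)
        self.alpha_ = self.selection_.alpha
        layer = decode(self.alpha_, X.shape[1], self.n_components)
        self.W_, self.b_ = layer.W, layer.b
        self.f1_, self.f2_ = self.selection_.f1, self.selection_.f2
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Learned nonlinear features g(X W_F + b_F), entries in (0, 1)."""
        check_is_fitted(self, "W_")
        X = check_array(X)
        layer = decode(self.alpha_, self.n_features_in_, self.n_components)
        return hidden_output(X, layer)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "W_")
        return {
            "format": "emoelm-model",
            "version": 1,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "strategy": self.strategy,
            "seed": self.random_state,
            "n_features_in": int(self.n_features_in_),
            "selected": {
                "index": int(self.selection_.index),
                "f1": self.f1_,
                "f2": self.f2_,
            },
            "alpha": self.alpha_.tolist(),
            "W": self.W_.tolist(),
            "b": self.b_.tolist(),
            "archive": np.asarray(self.archive_.F).tolist(),
        }

    def save(self, path) -> None:
        """Write the fitted model as deterministic JSON."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "EMOELM":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "emoelm-model":
            raise ValueError(f"{path} is not an emoelm model file")
        params = dict(doc["config"])
        params["bounds"] = tuple(params["bounds"])
        model = cls(**params)
        model.alpha_ = np.asarray(doc["alpha"], dtype=float)
        model.W_ = np.asarray(doc["W"], dtype=float)
        model.b_ = np.asarray(doc["b"], dtype=float)
        model.f1_ = doc["selected"]["f1"]
        model.f2_ = doc["selected"]["f2"]
        model.n_features_in_ = doc["n_features_in"]
        model.archive_ = ParetoArchive(
            alphas=np.empty((len(doc["archive"]), 0)),
            F=np.asarray(doc["archive"], dtype=float),
        )
        return model


def l2l1_sparsity(F: np.ndarray, per_row: bool = True) -> float:
    """L2/L1 sparsity of a feature matrix; higher means sparser.

    Per sample the score ||f||_2 / ||f||_1 lies in [1/sqrt(L), 1]: a
    one-hot row scores 1, a uniform row scores 1/sqrt(L).  The default
    is the mean over rows; ``per_row=False`` scores the flattened matrix
    as one vector.  Zero rows carry no information and are skipped (with
    a warning).
    """
    F = np.asarray(F, dtype=float)
    if not per_row:
        l1 = np.abs(F).sum()
        if l1 == 0:
            raise ValueError("all-zero feature matrix has undefined sparsity")
        return float(np.linalg.norm(F) / l1)
    l1 = np.abs(F).sum(axis=1)
    keep = l1 > 0
    if not keep.any():
        raise ValueError("all-zero feature matrix has undefined sparsity")
    if not keep.all():
        warnings.warn(
            f"skipping {int((~keep).sum())} all-zero feature rows", UserWarning
        )
    l2 = np.linalg.norm(F[keep], axis=1)
    return float(np.mean(l2 / l1[keep]))


def classification_metrics(y_true, y_pred):
    """Overall accuracy, average accuracy, Cohen's kappa, per-class recalls.

    OA is the trace of the confusion matrix over the total; AA the mean
    of per-class recalls (classes absent from ``y_true`` are excluded
    with a warning); kappa corrects OA by the chance agreement p_e
    implied by the marginals.  Returns ``(oa, aa, kappa, per_class)``
    with ``per_class`` ordered by sorted class label.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    C = confusion_matrix(y_true, y_pred, labels=classes)
    total = C.sum()
    oa = np.trace(C) / total
    support = C.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(support > 0, np.diag(C) / support, np.nan)
    if np.isnan(per_class).any():
        warnings.warn(
            "classes absent from the truth labels are excluded from AA",
            UserWarning,
        )
    aa = float(np.nanmean(per_class))
    p_e = float((support / total) @ (C.sum(axis=0) / total))
    kappa = (oa - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return float(oa), aa, float(kappa), per_class


@dataclass
class EvaluationReport:
    """Mean +/- std of OA, AA, kappa and per-class accuracy over repeats."""

    classes: np.ndarray
    per_class_mean: np.ndarray
    per_class_std: np.ndarray
    oa_mean: float
    oa_std: float
    aa_mean: float
    aa_std: float
    kappa_mean: float
    kappa_std: float
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (str(c), m, s)
            for c, m, s in zip(
                self.classes, self.per_class_mean, self.per_class_std
            )
        ]
        rows += [
            ("OA", self.oa_mean, self.oa_std),
            ("AA", self.aa_mean, self.aa_std),
            ("Kappa", self.kappa_mean, self.kappa_std),
        ]
        return pd.DataFrame(rows, columns=["class", "mean", "std"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def __str__(self) -> str:
        lines = [
            f"{c:>8}: {m:.4f} +/- {s:.4f}"
            for c, m, s in zip(
                self.classes, self.per_class_mean, self.per_class_std
            )
        ]
        lines.append(f"      OA: {self.oa_mean:.4f} +/- {self.oa_std:.4f}")
        lines.append(f"      AA: {self.aa_mean:.4f} +/- {self.aa_std:.4f}")
        lines.append(
            f"   Kappa: {self.kappa_mean:.4f} +/- {self.kappa_std:.4f}"
        )
        return "\n".join(lines)


def evaluate_features(
    F: np.ndarray,
    labels,
    repeats: int = 10,
    train_fraction: float = 0.1,
    classifier_hidden: int = 500,
    lam: float = 1e6,
    seed=None,
) -> EvaluationReport:
    """Repeated stratified-split classification protocol.

    For each repeat: split ``train_fraction`` of the samples off for
    training (stratified by class), fit an ELM classifier with
    ``classifier_hidden`` neurons, predict the remainder, and record
    OA / AA / kappa / per-class accuracy.  Reports mean and std over
    repeats.  Every class needs at least 2 labeled samples.
    """
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels).ravel()
    if len(F) != len(labels):
        raise ValueError("feature rows and labels differ in length")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        bad = classes[counts < 2]
        raise ValueError(
            f"classes {bad.tolist()} have fewer than 2 labeled samples; "
            "stratified splitting is impossible"
        )
    ss = np.random.SeedSequence(seed)
    oas, aas, kappas, pcs = [], [], [], []
    for child in ss.spawn(repeats):
        s_split, s_clf = child.spawn(2)
        F_tr, F_te, y_tr, y_te = train_test_split(
            F,
            labels,
            train_size=train_fraction,
            stratify=labels,
            random_state=_child_seed(s_split),
        )
        clf = ELMClassifier(
            n_hidden=classifier_hidden,
            lam=lam,
            random_state=_child_seed(s_clf),
        ).fit(F_tr, y_tr)
        oa, aa, kappa, per_class = classification_metrics(y_te, clf.predict(F_te))
        oas.append(oa)
        aas.append(aa)
        kappas.append(kappa)
        pcs.append(per_class)
    pcs = np.asarray(pcs)
    return EvaluationReport(
        classes=classes,
        per_class_mean=np.nanmean(pcs, axis=0),
        per_class_std=np.nanstd(pcs, axis=0),
        oa_mean=float(np.mean(oas)),
        oa_std=float(np.std(oas)),
        aa_mean=float(np.mean(aas)),
        aa_std=float(np.std(aas)),
        kappa_mean=float(np.mean(kappas)),
        kappa_std=float(np.std(kappas)),
        n_repeats=repeats,
    )
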