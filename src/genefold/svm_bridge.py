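"""Soft-margin SVM on precomputed Gram matrices, plus bagging.

The kernel search is the contribution of this package; the quadratic
program itself is delegated to scikit-learn's SVC with
``kernel='precomputed'``.  What this module owns is the contract: the
fitted model stores the dual form — coefficients ``alpha_i y_i`` over
support vectors, bias ``b``, support row indices — and prediction is
``f(z) = sum_i alpha_i y_i K(x_i, z) + b`` recomputed from those stored
quantities, with ``sign(0) -> +1``.

``bagging_fit`` implements bootstrap-aggregated SVMs with majority vote
(odd member count, so no ties), usable with either an evolved kernel
expression or a preset kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .data_io import FeatureTable, kfold_split
from .errors import ConfigError, InputError
from .kernel import (
    BaselineKernelParams,
    GramMatrix,
    KernelExpression,
    baseline_gram,
    gram,
)

__all__ = [
    "SVMModel",
    "BaggedEnsemble",
    "train",
    "predict",
    "decision_scores",
    "cv_evaluate",
    "CVResult",
    "bagging_fit",
    "bagging_predict",
]


@dataclass
class SVMModel:
    """Dual form of a fitted soft-margin SVM on a precomputed kernel."""

    dual_coef: np.ndarray  # alpha_i * y_i per support vector
    bias: float
    support: np.ndarray  # row indices into the training set
    C: float
    n_train: int
    kernel_ref: dict | None = None

    def to_json_dict(self) -> dict:
        return {
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "support": self.support.tolist(),
            "C": self.C,
            "n_train": self.n_train,
            "kernel_ref": self.kernel_ref,
        }


def _as_matrix(g: GramMatrix | np.ndarray) -> np.ndarray:
    return g.values if isinstance(g, GramMatrix) else np.asarray(g, dtype=float)


def train(
    gram_train: GramMatrix | np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel_ref: dict | None = None,
) -> SVMModel:
    """Fit the soft-margin dual on a square symmetric training Gram."""
    K = _as_matrix(gram_train)
    y = np.asarray(labels, dtype=int)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError(f"training Gram must be square, got shape {K.shape}")
    if K.shape[0] != y.shape[0]:
        raise InputError("Gram size does not match the number of labels")
    if not np.allclose(K, K.T, atol=1e-8):
        raise InputError("training Gram is not symmetric; symmetrize it first")
    if len(np.unique(y)) < 2:
        raise InputError("training labels contain a single class")
    if C <= 0:
        raise InputError(f"C must be positive, got {C}")
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K, y)
    return SVMModel(
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        support=clf.support_.copy(),
        C=float(C),
        n_train=K.shape[0],
        kernel_ref=kernel_ref,
    )


def decision_scores(model: SVMModel, cross_gram: GramMatrix | np.ndarray) -> np.ndarray:
    """``f(z) = sum_i alpha_i y_i K(x_i, z) + b`` from the stored dual form."""
    K = _as_matrix(cross_gram)
    K = np.atleast_2d(K)
    if K.shape[1] != model.n_train:
        raise InputError(
            f"cross Gram has {K.shape[1]} columns, model was trained on {model.n_train} samples"
        )
    return K[:, model.support] @ model.dual_coef + model.bias


def predict(
    model: SVMModel, cross_gram: GramMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted +/-1 labels and raw decision scores; sign(0) -> +1."""
    scores = decision_scores(model, cross_gram)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


# ---------------------------------------------------------------------------
# cross-validated evaluation on a full square Gram
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Pooled held-out predictions from a stratified k-fold evaluation."""

    accuracy: float  # mean held-out accuracy over folds, as a fraction
    fold_accuracies: list[float]
    pred: np.ndarray  # pooled held-out +/-1 predictions, sample order
    scores: np.ndarray  # pooled held-out decision values, sample order


def cv_evaluate(
    K: GramMatrix | np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    folds=None,
) -> CVResult:
    """Stratified k-fold CV of a precomputed-kernel SVM on a square Gram.

    ``folds`` may carry a precomputed :class:`~genefold.data_io.FoldAssignment`
    so that several kernels are compared on identical partitions.
    """
    Km = _as_matrix(K)
    y = np.asarray(y, dtype=int)
    if folds is None:
        folds = kfold_split(y, k=k, seed=seed)
    pred = np.zeros_like(y)
    scores = np.zeros(len(y), dtype=float)
    accs = []
    for f in range(folds.k):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        model = train(Km[np.ix_(tr, tr)], y[tr], C=C)
        p, s = predict(model, Km[np.ix_(te, tr)])
        pred[te] = p
        scores[te] = s
        accs.append(float(np.mean(p == y[te])))
    return CVResult(
        accuracy=float(np.mean(accs)),
        fold_accuracies=accs,
        pred=pred,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

@dataclass
class BaggedEnsemble:
    """Bootstrap-aggregated precomputed-kernel SVMs with majority vote."""

    members: list[SVMModel]
    bootstrap_indices: list[np.ndarray]  # rows of the training set per member
    seed: int


def _full_gram(kernel, X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix from either an evolved expression or a preset spec.

    ``kernel`` is a :class:`KernelExpression`, or a tuple
    ``(name, BaselineKernelParams)`` naming a preset kernel.
    """
    if isinstance(kernel, KernelExpression):
        return gram(kernel, X, Z).values
    name, params = kernel
    return baseline_gram(name, X, Z if Z is not None else X, params)


def bagging_fit(
    data: FeatureTable,
    kernel,
    members: int = 11,
    C: float = 1.0,
    seed: int = 0,
    bootstrap: bool = True,
) -> BaggedEnsemble:
    """Train an odd-sized bagged ensemble on bootstrap resamples.

    Each member sees an ``n``-sample bootstrap of the training table
    (resampled until both classes are present).  ``bootstrap=False`` is a
    test hook making every member identical.
    """
    if members < 1 or members % 2 == 0:
        raise ConfigError(f"member count must be odd and >= 1, got {members}")
    if data.y is None:
        raise InputError("feature table labels are not encoded; call encode_labels first")
    n = data.n_samples
    K = _full_gram(kernel, data.X)
    rng = np.random.default_rng(int(seed))
    fitted: list[SVMModel] = []
    indices: list[np.ndarray] = []
    for _ in range(members):
        if bootstrap:
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(data.y[idx])) == 2:
                    break
        else:
            idx = np.arange(n)
        model = train(K[np.ix_(idx, idx)], data.y[idx], C=C)
        fitted.append(model)
        indices.append(idx)
    return BaggedEnsemble(members=fitted, bootstrap_indices=indices, seed=int(seed))


def bagging_predict(
    ensemble: BaggedEnsemble,
    kernel,
    train_data: FeatureTable,
    X_test: np.ndarray,
) -> np.ndarray:
    """Majority-vote +/-1 predictions of the ensemble on new samples."""
    cross = _full_gram(kernel, X_test, train_data.X)
    votes = np.zeros(cross.shape[0], dtype=int)
    for model, idx in zip(ensemble.members, ensemble.bootstrap_indices):
        p, _ = predict(model, cross[:, idx])
        votes += p
    return np.where(votes >= 0, 1, -1)
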