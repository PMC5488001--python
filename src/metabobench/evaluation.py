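"""Loss functions and error-estimation protocols.

Two empirical risks measure classifier accuracy. The misclassification
rate is the mean 0-1 loss of the argmax phenotype prediction. The
cross-entropy is the mean negative natural log of the predicted
probability of the true phenotype; unlike 0-1 loss it penalizes a
confidently wrong prediction (true-class probability 0.1%) far more than
a borderline one (49%). Predicted probabilities are floored before the
log so that a hard zero yields a large finite loss rather than infinity —
the floor is configurable because floor choice dominates the magnitude of
cross-entropy for classifiers that emit exact zeros (k-NN class
fractions, collapsed Naive Bayes posteriors).

``repeated_double_cv`` estimates generalization error for small datasets:
hyperparameters are tuned by inner cross-validation inside each outer
training fold (filtering and imputation refit there too, so nothing leaks
from held-out samples), losses are pooled over outer folds, and the whole
procedure is repeated over fresh random partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LossReport",
    "misclassification_rate",
    "cross_entropy",
    "repeated_double_cv",
    "PROB_FLOOR",
]

#: default floor on predicted probabilities inside the log
PROB_FLOOR = 1e-15

#: a pipeline fits on training data (tuning with `inner_folds`-fold CV under
#: `seed`) and returns test-class probabilities
Pipeline = Callable[[np.ndarray, np.ndarray, np.ndarray, int, int], np.ndarray]


@dataclass(frozen=True)
class LossReport:
    misclassification: float
    cross_entropy: float
    per_sample_zero_one: np.ndarray = field(repr=False)
    per_sample_cross_entropy: np.ndarray = field(repr=False)
    n: int = 0


def _check_probs(y_true: np.ndarray, prob_matrix: np.ndarray):
    y_true = np.asarray(y_true)
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if P.shape[0] != y_true.shape[0]:
        raise ValueError("probability matrix and labels disagree in length")
    classes = np.unique(y_true)
    if P.shape[1] < classes.size:
        raise ValueError("probability matrix has fewer columns than classes")
    return y_true, P


def misclassification_rate(y_true: np.ndarray, prob_matrix: np.ndarray) -> float:
    """Fraction of argmax predictions differing from the truth.

    Class columns are assumed ordered by sorted unique label; argmax ties
    resolve to the lowest class index (numpy convention).
    """
    y_true, P = _check_probs(y_true, prob_matrix)
    classes = np.unique(y_true)
    y_hat = classes[np.argmax(P[:, : classes.size], axis=1)]
    return float(np.mean(y_hat != y_true))


def cross_entropy(
    y_true: np.ndarray, prob_matrix: np.ndarray, floor: float = PROB_FLOOR
) -> float:
    """Mean -log predicted probability of the true class (natural log)."""
    y_true, P = _check_probs(y_true, prob_matrix)
    classes = np.unique(y_true)
    idx = np.searchsorted(classes, y_true)
    p_true = P[np.arange(len(y_true)), idx]
    return float(np.mean(-np.log(np.maximum(p_true, floor))))


def loss_report(
    y_true: np.ndarray, prob_matrix: np.ndarray, floor: float = PROB_FLOOR
) -> LossReport:
    y_true, P = _check_probs(y_true, prob_matrix)
    classes = np.unique(y_true)
    idx = np.searchsorted(classes, y_true)
    y_hat = classes[np.argmax(P[:, : classes.size], axis=1)]
    zo = (y_hat != y_true).astype(float)
    ce = -np.log(np.maximum(P[np.arange(len(y_true)), idx], floor))
    return LossReport(
        misclassification=float(zo.mean()),
        cross_entropy=float(ce.mean()),
        per_sample_zero_one=zo,
        per_sample_cross_entropy=ce,
        n=len(y_true),
    )


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for stratified CV")
    n_folds = min(n_folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError("stratification infeasible: a class has < 2 samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def repeated_double_cv(
    pipeline: Pipeline,
    X: np.ndarray,
    y: np.ndarray,
    outer_folds: int = 5,
    inner_folds: int = 5,
    repeats: int = 10,
    rng: np.random.Generator | None = None,
    floor: float = PROB_FLOOR,
) -> LossReport:
    """Repeated double (nested) cross-validation error estimate.

    The ``pipeline`` callable receives only the outer training part plus a
    seed (which it should use for its inner ``inner_folds``-fold tuning)
    and returns probabilities for the held-out part. Per-sample losses are
    pooled across outer folds, then averaged across ``repeats`` random
    partitions.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    zo_means, ce_means = [], []
    zo_all, ce_all = [], []
    for _ in range(repeats):
        seed = int(rng.integers(2**31 - 1))
        folds = _stratified_folds(y, outer_folds, seed)
        zo_rep, ce_rep = [], []
        for f, (tr, te) in enumerate(folds):
            P = pipeline(X[tr], y[tr], X[te], seed + f + 1, inner_folds)
            rep = loss_report(y[te], P, floor=floor)
            zo_rep.append(rep.per_sample_zero_one)
            ce_rep.append(rep.per_sample_cross_entropy)
        zo_rep = np.concatenate(zo_rep)
        ce_rep = np.concatenate(ce_rep)
        zo_means.append(zo_rep.mean())
        ce_means.append(ce_rep.mean())
        zo_all.append(zo_rep)
        ce_all.append(ce_rep)
    return LossReport(
        misclassification=float(np.mean(zo_means)),
        cross_entropy=float(np.mean(ce_means)),
        per_sample_zero_one=np.concatenate(zo_all),
        per_sample_cross_entropy=np.concatenate(ce_all),
        n=len(y) * repeats,
    )
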