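"""Gaussian Naive Bayes and k-Nearest Neighbors, implemented directly.

Naive Bayes: posterior P(c_g | x) proportional to the class prior times
the product over metabolites of Gaussian class-conditional densities,
whose means and variances are per-class maximum-likelihood estimates.
Accumulation is in log space and variances are floored so that a
metabolite constant within a class cannot produce a degenerate density.

k-NN: the posterior of class g at a query point is the fraction of its k
nearest training samples (Euclidean distance) carrying label g. Distance
ties at the k-th neighbor are resolved toward the lowest training-row
index, which makes predictions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NBModel", "KNNModel", "fit_nb", "fit_predict_nb", "fit_predict_knn"]

#: relative variance floor (fraction of the pooled variance)
NB_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class NBModel:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray = field(repr=False)  # G x p
    variances: np.ndarray = field(repr=False)  # G x p


@dataclass(frozen=True)
class KNNModel:
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    classes: np.ndarray
    k: int


def fit_nb(X_train: np.ndarray, y_train: np.ndarray) -> NBModel:
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    G, p = classes.size, X.shape[1]
    priors = np.empty(G)
    means = np.empty((G, p))
    variances = np.empty((G, p))
    pooled = X.var(axis=0)  # MLE over all samples
    floor = NB_VAR_FLOOR * max(float(pooled.mean()), np.finfo(float).tiny)
    for g, cls in enumerate(classes):
        Xg = X[y == cls]
        if Xg.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        priors[g] = Xg.shape[0] / X.shape[0]
        means[g] = Xg.mean(axis=0)
        variances[g] = np.maximum(Xg.var(axis=0), floor)  # MLE, floored
    return NBModel(classes=classes, priors=priors, means=means, variances=variances)


def predict_nb(model: NBModel, X_new: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    log_post = np.log(model.priors)[None, :] + np.stack(
        [
            -0.5
            * (
                np.log(2.0 * np.pi * model.variances[g])[None, :]
                + (X - model.means[g][None, :]) ** 2 / model.variances[g][None, :]
            ).sum(axis=1)
            for g in range(model.classes.size)
        ],
        axis=1,
    )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    return post / post.sum(axis=1, keepdims=True)


def fit_predict_nb(
    X_train: np.ndarray, y_train: np.ndarray, X_new: np.ndarray
) -> np.ndarray:
    """Gaussian NB posteriors for new samples (rows sum to one)."""
    return predict_nb(fit_nb(X_train, y_train), X_new)


def fit_predict_knn(
    X_train: np.ndarray, y_train: np.ndarray, X_new: np.ndarray, k: int
) -> np.ndarray:
    """k-NN class-fraction posteriors (each probability a multiple of 1/k).

    Euclidean metric; neighbor sets resolved by (distance, training index)
    lexicographic order so results are reproducible under distance ties.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    n = X_train.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    classes = np.unique(y_train)
    labels = np.searchsorted(classes, y_train)
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ X_train.T
        + (X_train**2).sum(axis=1)[None, :]
    )
    # stable sort on distance keeps lowest training index first among ties
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    counts = np.zeros((X.shape[0], classes.size))
    for g in range(classes.size):
        counts[:, g] = (labels[nearest] == g).sum(axis=1)
    return counts / float(k)
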