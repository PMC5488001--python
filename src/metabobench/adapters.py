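"""Contract-specified adapters for SVM, Random Forest and neural networks.

The support-vector machine and random forest delegate their solvers to
scikit-learn under explicit contracts: the SVM uses a Gaussian kernel
K(x, x') = exp(-gamma ||x - x'||^2) with one-against-one multiclass
aggregation and pairwise-coupled probability outputs; the forest is an
ensemble of 1000 fully grown trees with a per-split random subspace of
``mtry`` metabolites, whose predicted probabilities are tree-vote
fractions (fully grown trees have pure leaves, so scikit-learn's averaged
leaf distributions reduce to vote fractions).

The feedforward network is trained in-house: logistic hidden layers,
softmax output, cross-entropy error, and iRPROP- ("resilient
backpropagation") weight updates, which adapt a per-weight step size from
the sign of successive partial derivatives and are insensitive to
gradient magnitude. No pre-installed backend offers RPROP training, hence
the numpy implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "RFConfig",
    "NNetConfig",
    "gaussian_kernel",
    "fit_predict_svm",
    "fit_predict_rf",
    "fit_predict_nnet",
]

log = logging.getLogger(__name__)

RF_N_TREES = 1000
NNET_NODE_GRID = tuple(range(15, 101, 5))
NNET_LAYER_GRID = (1, 2)


@dataclass(frozen=True)
class SVMConfig:
    """Gaussian-kernel soft-margin SVM; only the bandwidth is tuned."""

    gamma: float
    cost: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not self.cost > 0:
            raise ValueError("cost must be > 0")


@dataclass(frozen=True)
class RFConfig:
    """Random forest: fixed ensemble size, tuned random-subspace size."""

    mtry: int
    n_trees: int = RF_N_TREES

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass(frozen=True)
class NNetConfig:
    """Feedforward net: 1-2 logistic hidden layers, 15-100 nodes by 5."""

    n_hidden_layers: int = 1
    nodes_per_layer: int = 15

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in NNET_LAYER_GRID:
            raise ValueError("n_hidden_layers must be 1 or 2")
        if self.nodes_per_layer not in NNET_NODE_GRID:
            raise ValueError("nodes_per_layer must be in {15, 20, ..., 100}")


def gaussian_kernel(x: np.ndarray, x2: np.ndarray, gamma: float) -> float:
    """Radial kernel K(x, x') = exp(-gamma ||x - x'||^2)."""
    diff = np.asarray(x, dtype=float) - np.asarray(x2, dtype=float)
    return float(np.exp(-gamma * np.dot(diff, diff)))


def _standardize(X_train: np.ndarray, X_new: np.ndarray):
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (X_train - mean) / scale, (X_new - mean) / scale


def fit_predict_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_new: np.ndarray,
    config: SVMConfig,
    seed: int = 0,
) -> np.ndarray:
    """One-against-one Gaussian-kernel SVM probabilities on new samples.

    Columns are standardized on the training statistics before fitting
    (the usual SVM preprocessing, and what keeps the bandwidth grids
    scale-comparable across datasets).
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("need at least two classes")
    Xt, Xn = _standardize(
        np.asarray(X_train, dtype=float), np.atleast_2d(np.asarray(X_new, float))
    )
    with warnings.catch_warnings():
        # keep SVC's internal one-vs-one pairwise-coupled Platt probabilities
        warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(
            C=config.cost,
            kernel="rbf",
            gamma=config.gamma,
            probability=True,
            random_state=int(seed),
        )
        clf.fit(Xt, y_train)
    return clf.predict_proba(Xn)


def fit_predict_rf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_new: np.ndarray,
    config: RFConfig,
    seed: int = 0,
) -> np.ndarray:
    """1000-tree random forest; probabilities are tree-vote fractions.

    A single-class training set is legal: every tree votes that class,
    so probability 1 is returned for any query.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if config.mtry > X_train.shape[1]:
        raise ValueError(
            f"mtry={config.mtry} exceeds metabolite count {X_train.shape[1]}"
        )
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.mtry,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X_train, y_train)
    return clf.predict_proba(np.atleast_2d(np.asarray(X_new, float)))


# ---------------------------------------------------------------------------
# feedforward network with iRPROP- training

_ETA_PLUS = 1.2
_ETA_MINUS = 0.5
_STEP_INIT = 0.0125
_STEP_MIN = 1e-8
_STEP_MAX = 5.0


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(X: np.ndarray, weights: list[np.ndarray]):
    """Activations per layer; final layer is a row-stochastic softmax."""
    acts = [X]
    a = X
    for i, W in enumerate(weights):
        z = np.hstack([a, np.ones((a.shape[0], 1))]) @ W
        if i < len(weights) - 1:
            a = _logistic(z)
        else:
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)
        acts.append(a)
    return acts


def _gradients(acts, weights, Y):
    """Backpropagated cross-entropy gradients (softmax output)."""
    n = Y.shape[0]
    grads = [None] * len(weights)
    delta = (acts[-1] - Y) / n
    for i in range(len(weights) - 1, -1, -1):
        a_prev = np.hstack([acts[i], np.ones((acts[i].shape[0], 1))])
        grads[i] = a_prev.T @ delta
        if i > 0:
            back = delta @ weights[i][:-1].T  # drop the bias row
            delta = back * acts[i] * (1.0 - acts[i])
    return grads


def _train_rprop(X, Y, layer_sizes, rng, max_epochs):
    """Full-batch iRPROP- training; returns weights or None on divergence."""
    weights = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in + 1, fan_out))
        weights.append(W)
    steps = [np.full_like(W, _STEP_INIT) for W in weights]
    prev_grads = [np.zeros_like(W) for W in weights]
    prev_loss = np.inf
    for _ in range(max_epochs):
        acts = _forward(X, weights)
        probs = np.clip(acts[-1], 1e-12, None)
        loss = -np.log(probs[Y.astype(bool)]).mean()
        if not np.isfinite(loss):
            return None
        if prev_loss - loss < 1e-9 and loss < prev_loss:
            break
        prev_loss = min(prev_loss, loss)
        grads = _gradients(acts, weights, Y)
        for W, g, gp, st in zip(weights, grads, prev_grads, steps):
            sign_change = g * gp
            st *= np.where(
                sign_change > 0, _ETA_PLUS, np.where(sign_change < 0, _ETA_MINUS, 1.0)
            )
            np.clip(st, _STEP_MIN, _STEP_MAX, out=st)
            g_eff = np.where(sign_change < 0, 0.0, g)  # iRPROP-: forget on flip
            W -= np.sign(g_eff) * st
            gp[...] = g_eff
    return weights


def fit_predict_nnet(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_new: np.ndarray,
    config: NNetConfig,
    seed: int = 0,
    max_epochs: int = 300,
) -> np.ndarray:
    """Feedforward-network probabilities, resilient-backpropagation trained.

    Inputs are standardized on training statistics; targets are one-hot.
    On numerical divergence, training restarts with a fresh initialization
    up to three times, after which uniform probabilities are returned with
    a warning.
    """
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    Xt, Xn = _standardize(
        np.asarray(X_train, dtype=float), np.atleast_2d(np.asarray(X_new, float))
    )
    Y = (y_train[:, None] == classes[None, :]).astype(float)
    sizes = (
        [Xt.shape[1]]
        + [config.nodes_per_layer] * config.n_hidden_layers
        + [classes.size]
    )
    rng = np.random.default_rng(int(seed))
    for _ in range(3):
        weights = _train_rprop(Xt, Y, sizes, rng, max_epochs)
        if weights is not None:
            return _forward(Xn, weights)[-1]
    log.warning("network training diverged 3 times; returning uniform probabilities")
    return np.full((Xn.shape[0], classes.size), 1.0 / classes.size)
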