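"""Cross-validated grid search with kernel smoothing of the loss surface.

Every classifier family is tuned the same way: for each candidate
parameter set on its published grid, the expected cross-entropy loss is
estimated by stratified k-fold cross-validation; the raw loss surface is
then smoothed over the grid by Nadaraya-Watson kernel regression (a
Gaussian kernel along each numeric axis, on the log scale for the SVM
bandwidth and the sPLS-DA regularization); the smoothed minimizer is the
selected parameter set. Smoothing damps the fold-to-fold Monte-Carlo
noise of individual grid points so a single lucky split cannot pick an
extreme parameter.

The full grids — 15 component counts, a 9-point regularization grid,
1000 log-spaced SVM bandwidths, 25 random-subspace sizes, 20 neighbor
counts, 36 network shapes — are expensive at desk scale, so every grid
can be subsampled to at most ``max_points`` evenly spaced candidates
("coarse" mode); selected parameters always remain on the published grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional

import numpy as np

from . import adapters, pls, simple
from .evaluation import cross_entropy, _stratified_folds

__all__ = [
    "GridAxis",
    "ParameterGrid",
    "TuningResult",
    "table4_grid",
    "cv_loss",
    "smooth_and_select",
    "tune",
    "TECHNIQUES",
    "TECHNIQUE_ORDER",
]

#: smoothing bandwidth as a multiple of the grid spacing
BANDWIDTH_FACTOR = 1.5

FitPredict = Callable[..., np.ndarray]


@dataclass(frozen=True)
class GridAxis:
    name: str
    values: tuple
    scale: str = "linear"  # linear | log | categorical


@dataclass(frozen=True)
class ParameterGrid:
    classifier: str
    axes: tuple[GridAxis, ...]
    points: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("parameter grid must be non-empty")


@dataclass(frozen=True)
class TuningResult:
    grid: ParameterGrid
    raw_losses: np.ndarray = field(repr=False)
    smoothed_losses: np.ndarray = field(repr=False)
    selected: dict = field(default_factory=dict)
    fold_seed: int = 0


def _subsample(values: list, max_points: Optional[int]) -> list:
    if max_points is None or len(values) <= max_points:
        return values
    idx = np.unique(np.round(np.linspace(0, len(values) - 1, max_points)).astype(int))
    return [values[i] for i in idx]


def _make_grid(
    name: str, axes: list[GridAxis], max_points: Optional[int]
) -> ParameterGrid:
    points = [
        dict(zip([a.name for a in axes], combo))
        for combo in product(*[a.values for a in axes])
    ]
    points = _subsample(points, max_points)
    # retain only values still present after subsampling
    kept_axes = tuple(
        GridAxis(
            a.name,
            tuple(sorted({pt[a.name] for pt in points})),
            a.scale,
        )
        for a in axes
    )
    return ParameterGrid(classifier=name, axes=kept_axes, points=tuple(points))


def table4_grid(
    classifier: str,
    n_metabolites: Optional[int] = None,
    post_filter: bool = False,
    max_points: Optional[int] = None,
) -> ParameterGrid:
    """The published tuning grid for one classifier family.

    PLS-DA: components 1-15. sPLS-DA: components 1-15 x lambda 0.1-0.9 by
    0.1. SVM: 1000 log-spaced bandwidths, 10^[-5,-1] before significance
    filtering and 10^[-2,0] after. RF: ensemble fixed at 1000 trees,
    subspace size at 25 points spanning [5, p]. NNet: 1 or 2 hidden
    layers x 15-100 nodes by 5. k-NN: k = 1-20. NB has nothing to tune.
    ``max_points`` caps the grid by even subsampling.
    """
    c = classifier.lower()
    if c in ("pls-da", "plsda"):
        axes = [GridAxis("n_components", tuple(range(1, 16)))]
    elif c in ("spls-da", "splsda"):
        axes = [
            GridAxis("n_components", tuple(range(1, 16))),
            GridAxis("sparsity", tuple(np.round(np.arange(0.1, 0.95, 0.1), 10)), "log"),
        ]
    elif c == "svm":
        lo, hi = (-2.0, 0.0) if post_filter else (-5.0, -1.0)
        axes = [GridAxis("gamma", tuple(np.logspace(lo, hi, 1000)), "log")]
    elif c == "rf":
        if n_metabolites is None:
            raise ValueError("RF grid needs the metabolite count")
        lo = min(5, n_metabolites)
        vals = np.unique(np.round(np.linspace(lo, n_metabolites, 25)).astype(int))
        axes = [GridAxis("mtry", tuple(int(v) for v in vals))]
    elif c == "nnet":
        axes = [
            GridAxis("n_hidden_layers", (1, 2), "categorical"),
            GridAxis("nodes_per_layer", tuple(range(15, 101, 5))),
        ]
    elif c in ("k-nn", "knn"):
        axes = [GridAxis("k", tuple(range(1, 21)))]
    elif c == "nb":
        return ParameterGrid("NB", axes=(), points=({},))
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return _make_grid(classifier, axes, max_points)


def cv_loss(
    fit_predict: FitPredict,
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    fold_seed: Optional[int] = None,
) -> float:
    """Mean held-out cross-entropy of one parameter set, stratified k-fold.

    ``fit_predict(X_tr, y_tr, X_te, seed=..., **params)`` must return a
    row-stochastic probability matrix. A shared ``fold_seed`` makes fold
    assignments identical across the grid points of one tuning run.
    """
    if fold_seed is None:
        if rng is None:
            rng = np.random.default_rng()
        fold_seed = int(rng.integers(2**31 - 1))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _stratified_folds(y, n_folds, fold_seed)
    losses = []
    for f, (tr, te) in enumerate(folds):
        P = fit_predict(X[tr], y[tr], X[te], seed=fold_seed + f, **params)
        losses.append(cross_entropy(y[te], P))
    return float(np.mean(losses))


def _axis_coordinates(grid: ParameterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Numeric coordinates (n_points x n_axes) and per-axis bandwidths.

    Log-scaled axes are mapped through log10; categorical axes get NaN
    bandwidth, meaning only exact matches contribute weight.
    """
    pts = grid.points
    coords = np.zeros((len(pts), len(grid.axes)))
    bws = np.zeros(len(grid.axes))
    for j, ax in enumerate(grid.axes):
        if ax.scale == "categorical":
            vals = {v: i for i, v in enumerate(ax.values)}
            coords[:, j] = [vals[pt[ax.name]] for pt in pts]
            bws[j] = np.nan
            continue
        x = np.array([float(pt[ax.name]) for pt in pts])
        if ax.scale == "log":
            x = np.log10(x)
            uniq = np.log10(np.array(ax.values, dtype=float))
        else:
            uniq = np.array(ax.values, dtype=float)
        coords[:, j] = x
        bws[j] = (
            BANDWIDTH_FACTOR * float(np.mean(np.diff(np.sort(uniq))))
            if uniq.size > 1
            else np.inf
        )
    return coords, bws


def smooth_and_select(
    grid: ParameterGrid,
    raw_losses: np.ndarray,
    fold_seed: int = 0,
) -> TuningResult:
    """Nadaraya-Watson smoothing of the CV loss surface, then argmin.

    Gaussian kernel per numeric axis with bandwidth 1.5x the grid
    spacing; categorical axes smooth only within a level. Ties at the
    minimum resolve to the earliest grid point, i.e. the smallest
    parameter values in axis order.
    """
    raw = np.asarray(raw_losses, dtype=float)
    if raw.shape != (len(grid.points),):
        raise ValueError("raw losses must align with grid points")
    if len(grid.points) == 1:
        return TuningResult(grid, raw, raw.copy(), dict(grid.points[0]), fold_seed)
    coords, bws = _axis_coordinates(grid)
    n = len(grid.points)
    logw = np.zeros((n, n))
    for j, bw in enumerate(bws):
        dx = coords[:, None, j] - coords[None, :, j]
        if np.isnan(bw):  # categorical: exact match only
            logw += np.where(dx == 0.0, 0.0, -np.inf)
        elif np.isfinite(bw):
            logw += -0.5 * (dx / bw) ** 2
    W = np.exp(logw)
    smoothed = (W @ raw) / W.sum(axis=1)
    # first minimum = smallest parameters; tolerance absorbs summation-order
    # float noise so exact ties on constant surfaces resolve deterministically
    tol = 1e-12 * max(1.0, float(np.abs(smoothed).max()))
    best = int(np.flatnonzero(smoothed <= smoothed.min() + tol)[0])
    return TuningResult(grid, raw, smoothed, dict(grid.points[best]), fold_seed)


def tune(
    fit_predict: FitPredict,
    grid: ParameterGrid,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> TuningResult:
    """Grid CV + smoothing for one classifier on one training set."""
    if rng is None:
        rng = np.random.default_rng()
    fold_seed = int(rng.integers(2**31 - 1))
    raw = np.array(
        [
            cv_loss(fit_predict, X, y, pt, n_folds=n_folds, fold_seed=fold_seed)
            for pt in grid.points
        ]
    )
    return smooth_and_select(grid, raw, fold_seed)


# ---------------------------------------------------------------------------
# shared fit-and-predict contract for the seven techniques


def _fp_plsda(X_tr, y_tr, X_te, seed=0, n_components=3):
    model = pls.fit_plsda(X_tr, y_tr, n_components=n_components)
    return pls.predict_plsda(model, X_te)


def _fp_splsda(X_tr, y_tr, X_te, seed=0, n_components=3, sparsity=0.5):
    model = pls.fit_splsda(X_tr, y_tr, n_components=n_components, sparsity=sparsity)
    return pls.predict_plsda(model, X_te)


def _fp_svm(X_tr, y_tr, X_te, seed=0, gamma=1e-3, cost=1.0):
    return adapters.fit_predict_svm(
        X_tr, y_tr, X_te, adapters.SVMConfig(gamma=gamma, cost=cost), seed=seed
    )


def _fp_rf(X_tr, y_tr, X_te, seed=0, mtry=5):
    mtry = min(int(mtry), X_tr.shape[1])
    return adapters.fit_predict_rf(
        X_tr, y_tr, X_te, adapters.RFConfig(mtry=mtry), seed=seed
    )


def _fp_nnet(X_tr, y_tr, X_te, seed=0, n_hidden_layers=1, nodes_per_layer=15):
    cfg = adapters.NNetConfig(
        n_hidden_layers=n_hidden_layers, nodes_per_layer=nodes_per_layer
    )
    return adapters.fit_predict_nnet(X_tr, y_tr, X_te, cfg, seed=seed)


def _fp_knn(X_tr, y_tr, X_te, seed=0, k=5):
    return simple.fit_predict_knn(X_tr, y_tr, X_te, k=min(int(k), len(y_tr)))


def _fp_nb(X_tr, y_tr, X_te, seed=0):
    return simple.fit_predict_nb(X_tr, y_tr, X_te)


#: fit-and-predict callables keyed by technique name (Table-1 naming)
TECHNIQUES: dict[str, FitPredict] = {
    "PLS-DA": _fp_plsda,
    "sPLS-DA": _fp_splsda,
    "SVM": _fp_svm,
    "NNet": _fp_nnet,
    "RF": _fp_rf,
    "k-NN": _fp_knn,
    "NB": _fp_nb,
}

TECHNIQUE_ORDER = tuple(TECHNIQUES)
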