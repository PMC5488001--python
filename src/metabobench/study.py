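"""Orchestration of simulation studies and aggregation of their results.

One study = one simulated dataset, split into equal train and test
halves. Each of the seven classifier families is evaluated twice: on all
metabolites ("pre" filter state) and on the metabolites surviving
univariate significance filtering fit on the training half only ("post").
Within each arm the family's parameters are tuned by inner
cross-validation on the training half, the tuned classifier is refit on
the whole training half, and both losses are computed on the untouched
test half. Missing values are imputed (half-minimum, training statistics
applied to each half separately by refitting) before anything else sees
the data.

Studies are mutually independent: study b of a run with master seed S
uses the b-th child of ``numpy.random.SeedSequence(S)``, so results do
not depend on execution order or batching.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .evaluation import cross_entropy, misclassification_rate
from .filtering import significance_filter
from .simulate import SimulationConfig, impute_missing, simulate_dataset
from .tuning import TECHNIQUES, table4_grid, tune

__all__ = [
    "CellResult",
    "StudyResult",
    "run_study",
    "run_studies",
    "aggregate_summary",
    "pairwise_win_matrix",
    "results_to_frame",
]

log = logging.getLogger(__name__)

FILTER_STATES = ("pre", "post")


@dataclass(frozen=True)
class CellResult:
    """Losses of one technique in one filter state of one study."""

    technique: str
    filter_state: str
    misclassification: Optional[float] = None
    cross_entropy: Optional[float] = None
    selected_params: dict = field(default_factory=dict)
    failed: bool = False
    error: str = ""


@dataclass(frozen=True)
class StudyResult:
    study_id: int
    seed: int
    scenario: str
    cells: tuple[CellResult, ...]
    n_kept_post_filter: int = 0
    n_train: int = 0
    n_test: int = 0

    def cell(self, technique: str, filter_state: str) -> CellResult:
        for c in self.cells:
            if c.technique == technique and c.filter_state == filter_state:
                return c
        raise KeyError((technique, filter_state))


def _evaluate_arm(
    X_tr,
    y_tr,
    X_te,
    y_te,
    filter_state: str,
    techniques: Sequence[str],
    rng: np.random.Generator,
    n_folds: int,
    max_grid_points: Optional[int],
) -> list[CellResult]:
    cells = []
    p = X_tr.shape[1]
    for name in techniques:
        fit_predict = TECHNIQUES[name]
        try:
            grid = table4_grid(
                name,
                n_metabolites=p,
                post_filter=(filter_state == "post"),
                max_points=max_grid_points,
            )
            result = tune(fit_predict, grid, X_tr, y_tr, n_folds=n_folds, rng=rng)
            seed = int(rng.integers(2**31 - 1))
            P = fit_predict(X_tr, y_tr, X_te, seed=seed, **result.selected)
            cells.append(
                CellResult(
                    technique=name,
                    filter_state=filter_state,
                    misclassification=misclassification_rate(y_te, P),
                    cross_entropy=cross_entropy(y_te, P),
                    selected_params=result.selected,
                )
            )
        except Exception as exc:  # record the failure, keep the study going
            log.warning("%s/%s failed: %s", name, filter_state, exc)
            cells.append(
                CellResult(
                    technique=name,
                    filter_state=filter_state,
                    failed=True,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return cells


def run_study(
    config: SimulationConfig,
    seed: int,
    study_id: int = 0,
    techniques: Sequence[str] = tuple(TECHNIQUES),
    filter_states: Sequence[str] = FILTER_STATES,
    n_folds: int = 5,
    max_grid_points: Optional[int] = None,
    test_fraction: float = 0.5,
) -> StudyResult:
    """Run one complete simulation study; deterministic in (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dataset = simulate_dataset(config, rng)
    imp = impute_missing(dataset.X)
    X, y = imp.X, dataset.y

    split_seed = int(rng.integers(2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=split_seed
    )

    cells: list[CellResult] = []
    n_kept = 0
    for state in filter_states:
        if state == "pre":
            Xtr_s, Xte_s = X_tr, X_te
        else:
            method = "t" if config.scenario == "baseline" else "wilcoxon"
            kept = significance_filter(X_tr, y_tr, method=method)
            n_kept = len(kept)
            Xtr_s, Xte_s = X_tr[:, kept], X_te[:, kept]
        cells.extend(
            _evaluate_arm(
                Xtr_s, y_tr, Xte_s, y_te, state, techniques, rng,
                n_folds, max_grid_points,
            )
        )
    return StudyResult(
        study_id=study_id,
        seed=seed,
        scenario=config.scenario,
        cells=tuple(cells),
        n_kept_post_filter=n_kept,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def run_studies(
    config: SimulationConfig,
    n_studies: int,
    master_seed: int,
    techniques: Sequence[str] = tuple(TECHNIQUES),
    filter_states: Sequence[str] = FILTER_STATES,
    n_folds: int = 5,
    max_grid_points: Optional[int] = None,
    progress: bool = False,
) -> list[StudyResult]:
    """Run B independent studies from one master seed.

    Study b draws its seed from the b-th spawn of the master seed
    sequence, so any subset of studies can be reproduced in isolation.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_studies)
    results = []
    for b, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        t0 = time.time()
        results.append(
            run_study(
                config,
                seed,
                study_id=b,
                techniques=techniques,
                filter_states=filter_states,
                n_folds=n_folds,
                max_grid_points=max_grid_points,
            )
        )
        if progress:
            log.info("study %d/%d done in %.1fs", b + 1, n_studies, time.time() - t0)
    return results


def make_pipeline(
    technique: str,
    filter_state: str = "post",
    filter_method: str = "wilcoxon",
    max_grid_points: Optional[int] = None,
):
    """Tune-and-predict pipeline callable for nested CV on real data.

    Everything data-dependent — imputation, significance filtering,
    parameter tuning — is refit on the training part it receives, so the
    held-out part never influences model selection.
    """
    fit_predict = TECHNIQUES[technique]

    def pipeline(X_tr, y_tr, X_te, seed, inner_folds=5):
        imp = impute_missing(X_tr)
        X_tr_c = imp.X
        X_te_c = np.asarray(X_te, dtype=float)[:, imp.kept]
        # test-half missing entries get the training-half fill values
        fill = np.nanmin(X_tr_c, axis=0)
        fill = fill - 0.5 * np.abs(fill)
        X_te_c = np.where(np.isnan(X_te_c), fill[None, :], X_te_c)
        if filter_state == "post":
            kept = significance_filter(X_tr_c, y_tr, method=filter_method)
            X_tr_c, X_te_c = X_tr_c[:, kept], X_te_c[:, kept]
        grid = table4_grid(
            technique,
            n_metabolites=X_tr_c.shape[1],
            post_filter=(filter_state == "post"),
            max_points=max_grid_points,
        )
        rng = np.random.default_rng(seed)
        result = tune(fit_predict, grid, X_tr_c, y_tr, n_folds=inner_folds, rng=rng)
        return fit_predict(
            X_tr_c, y_tr, X_te_c, seed=int(rng.integers(2**31 - 1)),
            **result.selected,
        )

    return pipeline


def evaluate_real(
    X: np.ndarray,
    y: np.ndarray,
    protocol: str = "train-test",
    techniques: Sequence[str] = tuple(TECHNIQUES),
    filter_states: Sequence[str] = FILTER_STATES,
    filter_method: str = "wilcoxon",
    seed: int = 0,
    max_grid_points: Optional[int] = None,
    test_fraction: float = 1.0 / 3.0,
    outer_folds: int = 5,
    inner_folds: int = 5,
    repeats: int = 3,
) -> pd.DataFrame:
    """Run the benchmarking pipeline on a user-supplied abundance table.

    ``protocol="train-test"`` withholds a stratified third of the samples
    as a test set; ``"double-cv"`` estimates error by repeated double
    cross-validation (for datasets too small to split). Returns a tidy
    frame of both losses per technique x filter state.
    """
    from .evaluation import repeated_double_cv

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rows = []
    rng = np.random.default_rng(seed)
    if protocol == "train-test":
        split_seed = int(rng.integers(2**31 - 1))
        tr, te = train_test_split(
            np.arange(len(y)), test_size=test_fraction, stratify=y,
            random_state=split_seed,
        )
        for state in filter_states:
            for name in techniques:
                pipe = make_pipeline(name, state, filter_method, max_grid_points)
                P = pipe(X[tr], y[tr], X[te], int(rng.integers(2**31 - 1)),
                         inner_folds)
                rows.append(
                    {
                        "technique": name,
                        "filter_state": state,
                        "misclassification": misclassification_rate(y[te], P),
                        "cross_entropy": cross_entropy(y[te], P),
                    }
                )
    elif protocol == "double-cv":
        for state in filter_states:
            for name in techniques:
                pipe = make_pipeline(name, state, filter_method, max_grid_points)
                rep = repeated_double_cv(
                    pipe, X, y, outer_folds=outer_folds,
                    inner_folds=inner_folds, repeats=repeats, rng=rng,
                )
                rows.append(
                    {
                        "technique": name,
                        "filter_state": state,
                        "misclassification": rep.misclassification,
                        "cross_entropy": rep.cross_entropy,
                    }
                )
    else:
        raise ValueError("protocol must be 'train-test' or 'double-cv'")
    return pd.DataFrame(rows)


def results_to_frame(results: Iterable[StudyResult]) -> pd.DataFrame:
    """Tidy per-study records: one row per study x technique x filter state."""
    rows = []
    for r in results:
        for c in r.cells:
            rows.append(
                {
                    "study_id": r.study_id,
                    "seed": r.seed,
                    "scenario": r.scenario,
                    "technique": c.technique,
                    "filter_state": c.filter_state,
                    "misclassification": c.misclassification,
                    "cross_entropy": c.cross_entropy,
                    "failed": c.failed,
                    "selected_params": repr(c.selected_params),
                    "n_kept_post_filter": r.n_kept_post_filter,
                }
            )
    return pd.DataFrame(rows)


def aggregate_summary(results: Sequence[StudyResult]) -> pd.DataFrame:
    """Mean, SD, median and IQR of both losses per technique x filter state.

    Misclassification is reported on the 0-100 percent scale. Quantiles
    use linear interpolation (type 7). Failed cells are excluded pairwise
    and the surviving count reported per cell.
    """
    if not results:
        raise ValueError("need at least one study result")
    df = results_to_frame(results)
    df = df[~df["failed"]]
    df["misclassification"] = df["misclassification"] * 100.0

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for loss in ("misclassification", "cross_entropy"):
            v = g[loss].to_numpy(dtype=float)
            out[f"{loss}_mean"] = float(np.mean(v))
            out[f"{loss}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            out[f"{loss}_median"] = float(np.median(v))
            q1, q3 = np.quantile(v, [0.25, 0.75])
            out[f"{loss}_iqr"] = float(q3 - q1)
        out["n_studies"] = len(g)
        return pd.Series(out)

    grouped = (
        df.groupby(["scenario", "filter_state", "technique"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return grouped


def pairwise_win_matrix(
    results: Sequence[StudyResult],
    loss: str = "misclassification",
    scenario: Optional[str] = None,
    filter_state: str = "post",
) -> pd.DataFrame:
    """Proportion of studies in which technique a beat technique b.

    Entry (a, b) counts studies with loss_a < loss_b, ties contributing
    0.5 to each side; the diagonal is NaN. Studies where either cell
    failed are excluded pairwise.
    """
    if loss not in ("misclassification", "cross_entropy"):
        raise ValueError("loss must be 'misclassification' or 'cross_entropy'")
    df = results_to_frame(results)
    df = df[(~df["failed"]) & (df["filter_state"] == filter_state)]
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    wide = df.pivot_table(index="study_id", columns="technique", values=loss)
    names = [t for t in TECHNIQUES if t in wide.columns] + sorted(
        c for c in wide.columns if c not in TECHNIQUES
    )
    M = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            pair = wide[[a, b]].dropna()
            if pair.empty:
                continue
            wins = (pair[a] < pair[b]).sum() + 0.5 * (pair[a] == pair[b]).sum()
            M.loc[a, b] = wins / len(pair)
    return M
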