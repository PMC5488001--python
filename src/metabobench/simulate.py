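"""Simulated untargeted-metabolomics datasets with known ground truth.

Abundances are generated in K independent blocks of d metabolites each,
mimicking discrete biological processes: every block gets a random
positive-definite correlation matrix from the C-vine sampler and rows are
drawn multivariate normal with phenotype-specific means. A reference
phenotype has mean zero everywhere; each comparator phenotype perturbs a
small random subset of blocks, with block effect sizes drawn from a
hierarchical model (exponential magnitude, random sign, per-metabolite
normal scatter).

The "realistic" scenario layers four artifacts of real data on top of the
multivariate-normal baseline, in order: biological outliers (whole-block
shifts for a sample), technical outliers (single-metabolite shifts),
non-normal marginals via a generalized-Gaussian quantile transform of the
empirical CDF, and missing values from an artificial limit of detection
(MNAR: an entry is missing because its value is low). Class sizes are
unbalanced via a Dirichlet-multinomial draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtri

from .vine import CorrelationMatrix, sample_correlation_matrix

__all__ = [
    "SimulationConfig",
    "PhenotypeMeans",
    "SimulatedDataset",
    "ImputationResult",
    "draw_perturbed_means",
    "draw_phenotype_allocation",
    "simulate_baseline",
    "ggd_quantile",
    "apply_realistic_transforms",
    "simulate_dataset",
    "impute_missing",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulated study.

    Defaults follow the study design: 40 blocks x 25 metabolites
    (p = 1000), 3 phenotypes, comparator phenotypes perturbing
    DiscreteUnif(1,5) blocks with effect magnitudes theta ~ Exp(rate 1/2)
    (mean 2) and random sign. N = 120 samples per study (split 60/60 by
    the runner), a figure implied by the granularity of reported error
    rates rather than stated outright; see docs/methods.md.
    """

    n_blocks: int = 40
    block_size: int = 25
    n_phenotypes: int = 3
    total_samples: int = 120
    scenario: str = "baseline"
    eta: float = 1.0
    perturb_range: tuple[int, int] = (1, 5)
    theta_rate: float = 0.5
    sign_prob: float = 0.5
    ggd_kappa_range: tuple[float, float] = (-0.4, 0.4)
    ggd_alpha: float = 1.0
    outlier_rates: tuple[float, float] = (0.02, 0.01)
    outlier_magnitudes: tuple[float, float] = (4.0, 6.0)
    lod_quantile: float = 0.05
    dirichlet_alpha: tuple[float, ...] = (4.0, 4.0, 4.0)
    min_per_class: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario not in ("baseline", "realistic"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_blocks, self.block_size, self.n_phenotypes) < 1:
            raise ValueError("counts must be positive")
        for prob in (self.sign_prob, *self.outlier_rates):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.lod_quantile <= 0.5:
            raise ValueError("lod_quantile must lie in [0, 0.5]")
        if len(self.dirichlet_alpha) != self.n_phenotypes:
            raise ValueError("dirichlet_alpha must have one entry per phenotype")
        if self.total_samples < self.n_phenotypes * self.min_per_class:
            raise ValueError("total_samples must allow min_per_class per phenotype")

    @property
    def n_metabolites(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class PhenotypeMeans:
    """Ground-truth mean structure: which blocks differ and by how much.

    ``mu`` has one row per phenotype (row 0 is the reference, all zeros);
    ``perturbed_blocks[g]`` lists the block ids perturbed in phenotype g
    and ``theta[g]`` the signed block effect magnitudes, aligned.
    """

    perturbed_blocks: tuple[tuple[int, ...], ...]
    theta: tuple[tuple[float, ...], ...]
    mu: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SimulatedDataset:
    """One realized study: abundances, labels, masks and the truth."""

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    block_of: np.ndarray = field(repr=False)
    missing_mask: np.ndarray = field(repr=False)
    outlier_flags_biological: np.ndarray = field(repr=False)
    outlier_flags_technical: np.ndarray = field(repr=False)
    truth: PhenotypeMeans
    covariances: tuple[CorrelationMatrix, ...]
    scenario: str = "baseline"
    #: abundances before LOD masking (ground truth for the MNAR mechanism)
    X_premask: Optional[np.ndarray] = field(default=None, repr=False)
    #: per-metabolite limit-of-detection thresholds (NaN when no masking)
    lod_thresholds: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.X.shape[1]


def draw_perturbed_means(
    config: SimulationConfig, rng: np.random.Generator
) -> PhenotypeMeans:
    """Draw the hierarchical phenotype-mean structure.

    Per comparator phenotype: the number of perturbed blocks is discrete
    uniform on ``perturb_range``; each perturbed block k gets a magnitude
    theta_k ~ Exp(rate ``theta_rate``) with sign flipped with probability
    ``sign_prob``; metabolite means within the block are N(theta_k, 1).
    The reference phenotype (label 0) keeps mean zero everywhere.
    """
    p = config.n_metabolites
    lo, hi = config.perturb_range
    lo, hi = min(lo, config.n_blocks), min(hi, config.n_blocks)
    mu = np.zeros((config.n_phenotypes, p))
    blocks: list[tuple[int, ...]] = [()]
    thetas: list[tuple[float, ...]] = [()]
    for _ in range(1, config.n_phenotypes):
        n_pert = int(rng.integers(lo, hi + 1))
        chosen = np.sort(rng.choice(config.n_blocks, size=n_pert, replace=False))
        g_thetas = []
        row = np.zeros(p)
        for k in chosen:
            theta = rng.exponential(scale=1.0 / config.theta_rate)
            if rng.random() < config.sign_prob:
                theta = -theta
            cols = slice(k * config.block_size, (k + 1) * config.block_size)
            row[cols] = rng.normal(loc=theta, scale=1.0, size=config.block_size)
            g_thetas.append(float(theta))
        mu[len(blocks)] = row
        blocks.append(tuple(int(k) for k in chosen))
        thetas.append(tuple(g_thetas))
    return PhenotypeMeans(
        perturbed_blocks=tuple(blocks), theta=tuple(thetas), mu=mu
    )


def draw_phenotype_allocation(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-multinomial class counts, redrawn until every class is viable.

    Proportions ~ Dirichlet(alpha), counts ~ Multinomial(N, proportions);
    the draw is rejected until each class has at least ``min_per_class``
    samples, which every downstream stratified split relies on.
    """
    n, g = config.total_samples, config.n_phenotypes
    if n < g * config.min_per_class:
        raise ValueError("total_samples cannot satisfy min_per_class")
    while True:
        props = rng.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float))
        counts = rng.multinomial(n, props)
        if counts.min() >= config.min_per_class:
            return counts


def _balanced_allocation(config: SimulationConfig) -> np.ndarray:
    n, g = config.total_samples, config.n_phenotypes
    counts = np.full(g, n // g)
    counts[: n % g] += 1
    return counts


def simulate_baseline(
    config: SimulationConfig,
    rng: np.random.Generator,
    allocation: Optional[np.ndarray] = None,
) -> SimulatedDataset:
    """Simulate the multivariate-normal baseline dataset.

    K independent blocks; per block a fresh C-vine correlation matrix and
    N rows drawn MVN with the phenotype-specific means. Cross-block
    population correlation is exactly zero. Balanced class sizes unless an
    explicit allocation is supplied.
    """
    K, d, N = config.n_blocks, config.block_size, config.total_samples
    truth = draw_perturbed_means(config, rng)
    if allocation is None:
        allocation = _balanced_allocation(config)
    y = np.repeat(np.arange(config.n_phenotypes), allocation)
    rng.shuffle(y)

    X = np.empty((N, K * d))
    covs = []
    for k in range(K):
        corr = sample_correlation_matrix(d, config.eta, rng)
        L = np.linalg.cholesky(corr.entries)
        Z = rng.standard_normal((N, d))
        cols = slice(k * d, (k + 1) * d)
        X[:, cols] = Z @ L.T + truth.mu[y][:, cols]
        covs.append(corr)

    p = K * d
    return SimulatedDataset(
        X=X,
        y=y,
        block_of=np.repeat(np.arange(K), d),
        missing_mask=np.zeros((N, p), dtype=bool),
        outlier_flags_biological=np.zeros((N, K), dtype=bool),
        outlier_flags_technical=np.zeros((N, p), dtype=bool),
        truth=truth,
        covariances=tuple(covs),
        scenario="baseline",
    )


def ggd_quantile(u, kappa: float, alpha: float):
    """Quantile function of the zero-location generalized Gaussian (GGD).

    With z the standard-normal quantile of u, returns
    (alpha/kappa) * (1 - exp(-kappa * z)) for kappa != 0 and alpha * z at
    kappa = 0; the map is continuous in kappa. Positive kappa yields a
    right-bounded, left-skewed marginal and vice versa; kappa = 0 recovers
    the normal with scale alpha.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly in (0, 1)")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    z = ndtri(u)
    if abs(kappa) < 1e-12:
        out = alpha * z
    else:
        out = (alpha / kappa) * (1.0 - np.exp(-kappa * z))
    return out if out.ndim else float(out)


def apply_realistic_transforms(
    dataset: SimulatedDataset,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Layer outliers, non-normal marginals and MNAR missingness on a baseline.

    Order: (1) biological outliers — per (sample, block) with probability
    p_b, shift the sample's whole block by +/- the biological magnitude in
    column-SD units; (2) technical outliers — per (sample, metabolite)
    with probability p_t, analogous single-metabolite shifts; (3) per
    block draw one (kappa, alpha) and push every metabolite through the
    GGD quantile of its rescaled empirical CDF rank (rank/(n+1), a
    monotone, rank-preserving map); (4) per metabolite set the LOD at the
    pooled ``lod_quantile`` quantile and mask values strictly below it.
    """
    X = np.array(dataset.X)
    N, p = X.shape
    K, d = config.n_blocks, config.block_size
    p_b, p_t = config.outlier_rates
    mag_b, mag_t = config.outlier_magnitudes

    col_sd = X.std(axis=0, ddof=1)

    bio_flags = rng.random((N, K)) < p_b
    bio_signs = np.where(rng.random((N, K)) < 0.5, -1.0, 1.0)
    for k in range(K):
        cols = slice(k * d, (k + 1) * d)
        hit = bio_flags[:, k]
        X[hit, cols] += (mag_b * bio_signs[hit, k])[:, None] * col_sd[cols]

    tech_flags = rng.random((N, p)) < p_t
    tech_signs = np.where(rng.random((N, p)) < 0.5, -1.0, 1.0)
    X[tech_flags] += (mag_t * tech_signs * col_sd[None, :])[tech_flags]

    # block-wise GGD transform of the empirical CDF: non-normal marginals
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, N + 1)[:, None], axis=0)
    u = ranks / (N + 1.0)
    for k in range(K):
        cols = slice(k * d, (k + 1) * d)
        kappa = rng.uniform(*config.ggd_kappa_range)
        X[:, cols] = ggd_quantile(u[:, cols], kappa, config.ggd_alpha)

    X_premask = np.array(X)
    q = config.lod_quantile
    if q > 0.0:
        thresholds = np.quantile(X, q, axis=0)
        mask = X < thresholds[None, :]
        X = np.where(mask, np.nan, X)
    else:
        thresholds = np.full(p, np.nan)
        mask = np.zeros((N, p), dtype=bool)

    return replace(
        dataset,
        X=X,
        missing_mask=mask,
        outlier_flags_biological=bio_flags,
        outlier_flags_technical=tech_flags,
        scenario="realistic",
        X_premask=X_premask,
        lod_thresholds=thresholds,
    )


def simulate_dataset(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedDataset:
    """Simulate one study under the configured scenario.

    Baseline: balanced classes, MVN blocks, no missingness. Realistic:
    Dirichlet-multinomial unbalanced classes plus the outlier / GGD / LOD
    pipeline. Bit-identical for a fixed (config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.scenario == "baseline":
        return simulate_baseline(config, rng)
    allocation = draw_phenotype_allocation(config, rng)
    base = simulate_baseline(config, rng, allocation=allocation)
    return apply_realistic_transforms(base, config, rng)


@dataclass(frozen=True)
class ImputationResult:
    """Complete matrix after half-minimum imputation."""

    X: np.ndarray = field(repr=False)
    kept: np.ndarray = field(repr=False)
    dropped: np.ndarray = field(repr=False)


def impute_missing(X: np.ndarray) -> ImputationResult:
    """Replace missing entries by half the observed minimum of each column.

    Half-minimum imputation is the standard crude estimate for
    below-detection-limit abundances. For a positive column minimum m the
    fill value is m/2; in general it is m - |m|/2, which extends the rule
    to signed abundances (the GGD transform is centered at zero) while
    keeping the fill below the observed minimum, hence below the LOD in
    practice. Columns with no observed value at all are dropped and
    reported in ``dropped``.
    """
    X = np.asarray(X, dtype=float)
    observed = ~np.isnan(X)
    all_missing = ~observed.any(axis=0)
    kept = np.flatnonzero(~all_missing)
    dropped = np.flatnonzero(all_missing)
    Xk = X[:, kept]
    with np.errstate(all="ignore"):
        col_min = np.nanmin(Xk, axis=0)
    fill = np.broadcast_to(col_min - 0.5 * np.abs(col_min), Xk.shape)
    Xk = np.where(np.isnan(Xk), fill, Xk)
    return ImputationResult(X=Xk, kept=kept, dropped=dropped)
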