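"""Random positive-definite correlation matrices via the C-vine construction.

A C-vine organizes the d(d-1)/2 partial correlations of a d-variate
distribution in layers: layer k holds the partials rho_{k,i;1..k-1} between
variable k and each later variable i, conditioned on all earlier variables.
Drawing each partial from a stretched Beta(beta, beta) on (-1, 1), with beta
decreasing by 1/2 per layer from eta + (d-1)/2, yields the
Lewandowski-Kurowicka-Joe (LKJ) distribution over correlation matrices: at
eta = 1 the distribution is uniform over the space of valid correlation
matrices, and larger eta concentrates mass near the identity.

The construction is used here to give each simulated metabolite block a
random but guaranteed positive-definite dependence structure, including
higher-order partial correlations of the kind produced by feedback
regulation within biochemical pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PartialCorrelationVine",
    "CorrelationMatrix",
    "sample_partial_correlations",
    "vine_to_correlation",
    "correlation_to_vine",
    "sample_correlation_matrix",
]

#: smallest eigenvalue tolerated before a matrix is declared non-PD
PD_TOL = -1e-10
#: eigenvalue floor used when clipping marginally indefinite matrices
PD_CLIP = 1e-10


@dataclass(frozen=True)
class PartialCorrelationVine:
    """Triangular array of C-vine partial correlations.

    ``partials[k, i]`` (k < i) stores rho_{k+1, i+1; 1..k} in 1-based
    notation: the partial correlation of variables k and i given all
    variables before k. Entries with k >= i are unused and zero.
    """

    d: int
    eta: float
    partials: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"dimension must be >= 1, got {self.d}")
        if not self.eta > 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        p = np.asarray(self.partials, dtype=float)
        if p.shape != (self.d, self.d):
            raise ValueError("partials must be a d x d array")
        iu = np.triu_indices(self.d, k=1)
        vals = p[iu]
        if vals.size and not np.all((vals > -1.0) & (vals < 1.0)):
            raise ValueError("partial correlations must lie strictly in (-1, 1)")

    @property
    def n_partials(self) -> int:
        return self.d * (self.d - 1) // 2


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated correlation matrix: symmetric, unit diagonal, PD."""

    d: int
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (self.d, self.d):
            raise ValueError("entries must be d x d")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        off = m[np.triu_indices(self.d, k=1)]
        if off.size and np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(m).min() <= PD_TOL:
            raise ValueError("correlation matrix is not positive definite")

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.entries).min())


def sample_partial_correlations(
    d: int, eta: float, rng: np.random.Generator
) -> PartialCorrelationVine:
    """Draw the C-vine partial correlations of a random correlation matrix.

    beta starts at eta + (d-1)/2 and is decremented by 1/2 before each
    layer; every layer-k partial is Beta(beta, beta) on (0, 1) rescaled
    affinely to (-1, 1).

    Parameters
    ----------
    d : matrix dimension, >= 1.
    eta : LKJ concentration, > 0. eta = 1 is uniform over correlation
        matrices; larger values shrink correlations toward zero.
    rng : numpy random generator (no global state is touched).
    """
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    if not eta > 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    partials = np.zeros((d, d))
    beta = eta + (d - 1) / 2.0
    for k in range(d - 1):
        beta -= 0.5
        draws = rng.beta(beta, beta, size=d - k - 1)
        partials[k, k + 1 :] = 2.0 * draws - 1.0
    return PartialCorrelationVine(d=d, eta=eta, partials=partials)


def vine_to_correlation(vine: PartialCorrelationVine) -> CorrelationMatrix:
    """Invert the partial-correlation recursion to a full correlation matrix.

    The defining recursion expresses a deeper partial in terms of shallower
    ones,

        rho_{ij;kL} = (rho_{ij;L} - rho_{ik;L} rho_{jk;L})
                      / sqrt((1 - rho_{ik;L}^2)(1 - rho_{jk;L}^2));

    running it backwards, layer by layer, turns the vine's stored partials
    into plain correlations. The result is positive definite by
    construction whenever every partial lies in (-1, 1).
    """
    d = vine.d
    P = vine.partials
    R = np.eye(d)
    for k in range(d - 1):
        for i in range(k + 1, d):
            rho = P[k, i]
            # peel conditioning variables off, deepest first
            for ell in range(k - 1, -1, -1):
                rho = rho * np.sqrt(
                    (1.0 - P[ell, i] ** 2) * (1.0 - P[ell, k] ** 2)
                ) + P[ell, i] * P[ell, k]
            R[k, i] = R[i, k] = rho
    R = 0.5 * (R + R.T)
    w = np.linalg.eigvalsh(R)
    if w.min() <= PD_TOL:
        raise ArithmeticError(
            f"vine inversion produced a non-PD matrix (min eig {w.min():.3e})"
        )
    if w.min() < PD_CLIP:
        # marginally indefinite from floating point: clip and restore diagonal
        w2, V = np.linalg.eigh(R)
        R = (V * np.maximum(w2, PD_CLIP)) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
        R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(d=d, entries=R)


def correlation_to_vine(
    matrix: CorrelationMatrix, eta: float = 1.0
) -> PartialCorrelationVine:
    """Recover the C-vine partial correlations of a full correlation matrix.

    Applies the recursion in its forward direction; the round trip with
    :func:`vine_to_correlation` is the identity up to floating point.
    """
    d = matrix.d
    # work[k] holds correlations conditioned on variables 0..k-1
    cond = np.array(matrix.entries, dtype=float)
    P = np.zeros((d, d))
    for k in range(d - 1):
        P[k, k + 1 :] = cond[k, k + 1 :]
        nxt = np.array(cond)
        for i in range(k + 1, d):
            for j in range(k + 1, d):
                if i == j:
                    continue
                denom = np.sqrt((1.0 - cond[k, i] ** 2) * (1.0 - cond[k, j] ** 2))
                nxt[i, j] = (cond[i, j] - cond[k, i] * cond[k, j]) / denom
        cond = nxt
    return PartialCorrelationVine(d=d, eta=eta, partials=P)


def sample_correlation_matrix(
    d: int, eta: float, rng: np.random.Generator
) -> CorrelationMatrix:
    """Draw one random correlation matrix (vine sample + inversion)."""
    return vine_to_correlation(sample_partial_correlations(d, eta, rng))
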