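"""Depth-aware Bayesian correlations, classical baselines, and the kernel map.

The Bayesian correlation between entities ``i`` and ``j`` is the Pearson-type
correlation of their *latent* read fractions,

    r^b_ij = Cov(p_ic, p_jc) / sqrt(Var(p_ic) Var(p_jc)),

where covariance and variance are taken jointly over the condition ``c``
(uniform on its k values) and over the posterior Beta beliefs.  By the law of
total covariance, and because beliefs for different entities are independent
Betas, the numerator reduces to the covariance of the posterior means across
conditions; by the law of total variance, the denominator picks up an extra
``E(Var(p_ic|c))`` term — the average measurement uncertainty.  That extra
term is what shrinks correlations toward zero for imprecisely measured
(low-count, shallow-depth) entities while leaving well-measured entities
essentially at their Pearson value.

The correlation is a kernel for any strictly positive prior: each entity maps
to a unit vector ``psi_i`` (a normalized profile of posterior-mean deviations
plus one identity coordinate carrying the residual uncertainty mass) whose
inner products reproduce the correlation matrix, so the matrix is symmetric
positive semidefinite and usable in any kernel-based learner.

All-pairs computation is vectorized: centered posterior-mean cross-products
are a single m x k by k x m matrix product, giving O(m^2 k) work overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .count_model import (
    BeliefMatrices,
    CountMatrix,
    PriorSpec,
    compute_posterior,
    make_prior,
)

__all__ = [
    "CorrelationResult",
    "FeatureEmbedding",
    "bayes_correlation_pair",
    "bayes_correlation_matrix",
    "pearson_correlation_matrix",
    "spearman_correlation_matrix",
    "feature_embedding",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A symmetric m x m correlation matrix tagged with its method.

    ``matrix[i, j]`` is in ``[-1, 1]`` (NaN marks rows where a classical
    correlation is undefined); the diagonal is exactly 1 wherever defined.
    ``prior_scheme`` is ``None`` for the classical methods.
    """

    matrix: np.ndarray
    method: str
    prior_scheme: str | None
    entity_ids: tuple

    def to_dataframe(self):
        import pandas as pd

        ids = list(self.entity_ids)
        return pd.DataFrame(self.matrix, index=ids, columns=ids)


@dataclass(frozen=True)
class FeatureEmbedding:
    """Explicit feature-space witness of the kernel property.

    Attributes
    ----------
    g
        m x k deviations ``g_ic = E(p_ic|c) - E(p_ic)`` of the posterior
        means from their cross-condition average.
    V
        Length-m total variances ``V_i = Var(p_ic)`` (law of total variance).
    phi
        ``phi_i = g_i / sqrt(k V_i)``; the ``1/k`` condition weight of the
        covariance sum is folded into the normalization so that
        ``<phi_i, phi_j>`` equals the Bayesian correlation for ``i != j``.
    psi
        m x (k + m) unit vectors: ``phi_i`` followed by a single nonzero
        identity coordinate ``sqrt(1 - <phi_i, phi_i>)`` at position
        ``k + i``.  ``<psi_i, psi_j>`` reproduces the full correlation
        matrix, diagonal included.
    """

    g: np.ndarray
    V: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def gram(self) -> np.ndarray:
        """Inner-product (Gram) matrix of the psi vectors."""
        return self.psi @ self.psi.T


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _deviations(belief: BeliefMatrices) -> np.ndarray:
    """Centered posterior-mean profiles used in every covariance.

    For the ``zero_count`` prior the prior-mean contribution to ``E(p|c)``
    is the constant ``1/(2 + R_max)``; centering the data term alone is the
    same quantity with that constant cancelled exactly rather than to
    rounding error, which is what makes all-zero rows exactly uncorrelated.
    """
    base = belief.count_term if belief.scheme == "zero_count" else belief.post_mean
    return base - base.mean(axis=1, keepdims=True)


def _variance_parts(belief: BeliefMatrices, Z: np.ndarray):
    """Within-condition and across-condition variance components (1/k weights)."""
    within = belief.post_var.mean(axis=1)
    across = np.einsum("ij,ij->i", Z, Z) / belief.k
    return within, across


def _resolve_prior(R: CountMatrix, prior: PriorSpec | str) -> PriorSpec:
    if isinstance(prior, str):
        return make_prior(R, prior)
    return prior


# ---------------------------------------------------------------------------
# Bayesian correlation
# ---------------------------------------------------------------------------

def bayes_correlation_pair(belief: BeliefMatrices, i: int, j: int) -> float:
    """Bayesian correlation of entities ``i`` and ``j`` from their beliefs.

    Returns exactly 1.0 when ``i == j`` (the ratio degenerates to
    ``Var/Var``).  Otherwise evaluates the total-covariance formula; the
    within-condition covariance term is identically zero because beliefs for
    distinct entities are independent.
    """
    m = belief.m
    for idx in (i, j):
        if not (0 <= idx < m):
            raise IndexError(f"entity index {idx} out of range for m={m}")
    if i == j:
        return 1.0
    Z = _deviations(belief)
    k = belief.k
    cov = float(Z[i] @ Z[j]) / k
    wi = belief.post_var[i].mean()
    wj = belief.post_var[j].mean()
    vi = wi + float(Z[i] @ Z[i]) / k
    vj = wj + float(Z[j] @ Z[j]) / k
    r = cov / np.sqrt(vi * vj)
    return float(np.clip(r, -1.0, 1.0))


def bayes_correlation_matrix(
    R: CountMatrix,
    prior: PriorSpec | str = "zero_count",
    block_size: int | None = None,
) -> CorrelationResult:
    """All-pairs Bayesian correlation matrix (vectorized, O(m^2 k)).

    Parameters
    ----------
    R
        Count matrix; every condition must have positive depth.
    prior
        A :class:`PriorSpec` or one of the scheme names.
    block_size
        If given, the m x m result is assembled in row blocks of this many
        entities.  The output agrees to floating-point round-off (BLAS
        accumulation order differs); the peak additional memory drops
        from O(m^2) working copies to O(block_size * m), which matters once
        m reaches a few tens of thousands.
    """
    prior = _resolve_prior(R, prior)
    belief = compute_posterior(R, prior)
    Z = _deviations(belief)
    within, across = _variance_parts(belief, Z)
    sd = np.sqrt(within + across)
    k = belief.k

    m = belief.m
    if block_size is None:
        C = (Z @ Z.T) / k
        C /= np.outer(sd, sd)
    else:
        if block_size < 1:
            raise ValueError("block_size must be a positive integer")
        C = np.empty((m, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            blk = (Z[start:stop] @ Z.T) / k
            blk /= np.outer(sd[start:stop], sd)
            C[start:stop] = blk
    C = 0.5 * (C + C.T)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return CorrelationResult(
        matrix=C,
        method="bayes",
        prior_scheme=prior.scheme,
        entity_ids=R.entity_ids,
    )


# ---------------------------------------------------------------------------
# classical baselines on empirical read fractions
# ---------------------------------------------------------------------------

def _row_correlations(X: np.ndarray, method: str, entity_ids) -> CorrelationResult:
    """Pearson correlation of the rows of X, NaN for zero-variance rows."""
    m, k = X.shape
    degenerate = np.ptp(X, axis=1) == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} entity rows have zero variance across "
            f"conditions; their {method} correlations are undefined (NaN)",
            RuntimeWarning,
            stacklevel=3,
        )
    Z = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.einsum("ij,ij->i", Z, Z) / k)
    sd_safe = np.where(degenerate, np.nan, sd)
    C = (Z @ Z.T) / k
    C /= np.outer(sd_safe, sd_safe)
    C = 0.5 * (C + C.T)
    with np.errstate(invalid="ignore"):
        np.clip(C, -1.0, 1.0, out=C)
        # exactly proportional rows have r = 1 mathematically; snap values
        # a few ulps shy of +/-1 so perfect correlations read as exact
        snap = np.abs(np.abs(C) - 1.0) < 8e-15
    C[snap] = np.sign(C[snap])
    diag = np.where(degenerate, np.nan, 1.0)
    C[np.diag_indices(m)] = diag
    return CorrelationResult(
        matrix=C, method=method, prior_scheme=None, entity_ids=tuple(entity_ids))


def pearson_correlation_matrix(R: CountMatrix) -> CorrelationResult:
    """Pearson correlation of the empirical read fractions ``R_ic / R_c``.

    This is the depth-normalized classical baseline: invariant to scaling a
    row or the depths, and blind to measurement precision — a single stray
    read can produce a perfect correlation.
    """
    return _row_correlations(R.fractions, "pearson", R.entity_ids)


def spearman_correlation_matrix(R: CountMatrix) -> CorrelationResult:
    """Spearman (rank) correlation of the empirical read fractions.

    Rows are rank-transformed (average ranks on ties) and then correlated
    exactly as in :func:`pearson_correlation_matrix`.
    """
    ranks = rankdata(R.fractions, axis=1)
    return _row_correlations(ranks, "spearman", R.entity_ids)


# ---------------------------------------------------------------------------
# kernel feature map
# ---------------------------------------------------------------------------

def feature_embedding(belief: BeliefMatrices) -> FeatureEmbedding:
    """Explicit finite-dimensional feature map realizing the correlation kernel.

    The inner product of two distinct ``psi`` vectors is the Bayesian
    correlation; every ``psi_i`` has unit norm, so the Gram matrix equals the
    correlation matrix (diagonal included) and is positive semidefinite by
    construction.  The residual coordinate is real because the across-
    condition variance never exceeds the total variance.
    """
    Z = _deviations(belief)
    within, across = _variance_parts(belief, Z)
    V = within + across
    m, k = belief.m, belief.k
    phi = Z / np.sqrt(k * V)[:, None]
    # 1 - <phi_i, phi_i> = within_i / V_i >= 0, computed in that stable form
    tail = np.sqrt(within / V)
    psi = np.zeros((m, k + m))
    psi[:, :k] = phi
    psi[np.arange(m), k + np.arange(m)] = tail
    return FeatureEmbedding(g=Z, V=V, phi=phi, psi=psi)
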