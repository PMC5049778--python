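"""Count matrices, Beta priors, and posterior beliefs over true read fractions.

A sequencing experiment is summarized as an m x k matrix of non-negative
counts ``R``: rows are measured entities (genes, miRNAs, genomic regions),
columns are conditions (samples), and ``R_c`` is the sequencing depth of
condition ``c`` (its total attributed reads).  Each observed count is modeled
as ``R_ic ~ Binomial(R_c, p_ic)`` where ``p_ic`` is the latent fraction of
condition-``c`` reads attributable to entity ``i``.  Under an independent
conjugate ``Beta(a0_ic, b0_ic)`` prior for each cell, the posterior belief is
``Beta(a0_ic + R_ic, b0_ic + R_c - R_ic)``, whose mean and variance drive the
depth-aware correlation machinery in :mod:`bayescor.correlation`.

Three prior schemes are provided:

``uniform``
    ``a0 = b0 = 1`` — the flat prior.  Simple, but provably biased for
    low-count entities when depths are heterogeneous.
``dirichlet_marginal``
    ``a0 = 1/m``, ``b0 = 1 - 1/m`` — the marginal of a symmetric Dirichlet
    over all ``m`` entities, reflecting that a read has prior probability
    ``1/m`` (not ``1/2``) of coming from any one entity.
``zero_count``
    ``a0_ic = (R_c + 1)/(R_max + 1)``, ``b0 = 1`` with ``R_max`` the largest
    column total.  Designed so that an entity with zero counts everywhere is
    exactly uncorrelated with everything: the prior-mean contribution
    ``a0/(a0 + b0 + R_c) = 1/(2 + R_max)`` is constant across conditions and
    cancels out of every covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PRIOR_SCHEMES",
    "CountMatrix",
    "PriorSpec",
    "BeliefMatrices",
    "make_prior",
    "compute_posterior",
]

#: Recognized prior scheme names, in the order they are introduced above.
PRIOR_SCHEMES = ("uniform", "dirichlet_marginal", "zero_count")


def _as_2d_float(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"counts must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """An m x k matrix of non-negative (possibly fractional) read counts.

    Parameters
    ----------
    counts
        m x k array, ``counts[i, c]`` = reads attributed to entity ``i``
        under condition ``c``.  Fractional values are accepted as-is (read
        attribution is sometimes probabilistic).
    entity_ids, condition_ids
        Row and column labels.  Entity ids must be unique.
    column_totals
        Per-condition sequencing depths ``R_c``.  By default these are the
        column sums of ``counts``; pass them explicitly when the matrix holds
        only a subset of a larger transcriptome, in which case every cell
        must satisfy ``counts[i, c] <= column_totals[c]``.
    """

    counts: np.ndarray
    entity_ids: tuple
    condition_ids: tuple
    column_totals: np.ndarray

    def __init__(self, counts, entity_ids=None, condition_ids=None,
                 column_totals=None):
        counts = _as_2d_float(counts)
        m, k = counts.shape
        if m < 1 or k < 1:
            raise ValueError("count matrix must have at least one row and one column")
        if not np.all(np.isfinite(counts)):
            raise ValueError("count matrix contains non-finite values")
        if np.any(counts < 0):
            raise ValueError("count matrix contains negative values")

        if entity_ids is None:
            entity_ids = tuple(f"entity_{i + 1}" for i in range(m))
        else:
            entity_ids = tuple(str(e) for e in entity_ids)
        if condition_ids is None:
            condition_ids = tuple(f"cond_{c + 1}" for c in range(k))
        else:
            condition_ids = tuple(str(c) for c in condition_ids)
        if len(entity_ids) != m:
            raise ValueError(f"{len(entity_ids)} entity ids for {m} rows")
        if len(condition_ids) != k:
            raise ValueError(f"{len(condition_ids)} condition ids for {k} columns")
        if len(set(entity_ids)) != m:
            raise ValueError("entity ids must be unique")

        if column_totals is None:
            column_totals = counts.sum(axis=0)
        else:
            column_totals = np.asarray(column_totals, dtype=float)
            if column_totals.shape != (k,):
                raise ValueError("column_totals length must equal the number of conditions")
            if np.any(counts > column_totals[None, :]):
                raise ValueError("a count exceeds its condition's total depth")
        if np.any(column_totals < 0):
            raise ValueError("column totals must be non-negative")

        counts = counts.copy()
        counts.setflags(write=False)
        column_totals = column_totals.copy()
        column_totals.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "entity_ids", entity_ids)
        object.__setattr__(self, "condition_ids", condition_ids)
        object.__setattr__(self, "column_totals", column_totals)

    # -- basic geometry -------------------------------------------------
    @property
    def m(self) -> int:
        """Number of entities (rows)."""
        return self.counts.shape[0]

    @property
    def k(self) -> int:
        """Number of conditions (columns)."""
        return self.counts.shape[1]

    @property
    def r_max(self) -> float:
        """Largest column total (deepest condition)."""
        return float(self.column_totals.max())

    @property
    def r_min(self) -> float:
        """Smallest column total (shallowest condition)."""
        return float(self.column_totals.min())

    @property
    def row_totals(self) -> np.ndarray:
        """Total reads per entity, summed across conditions."""
        return self.counts.sum(axis=1)

    @property
    def fractions(self) -> np.ndarray:
        """Empirical read fractions ``R_ic / R_c`` (requires positive depths)."""
        self.require_positive_depths()
        return self.counts / self.column_totals[None, :]

    def require_positive_depths(self) -> None:
        """Raise if any condition has zero total counts.

        A zero-depth condition carries no evidence at all (the posterior is
        the bare prior) and empirical fractions are undefined, so correlation
        analysis refuses such columns.
        """
        if self.r_min <= 0:
            bad = [self.condition_ids[c]
                   for c in np.flatnonzero(self.column_totals <= 0)]
            raise ValueError(f"conditions with zero total counts: {bad}")

    def index_of(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(str(entity_id))
        except ValueError:
            raise KeyError(f"unknown entity id {entity_id!r}") from None

    # -- optional preprocessing (off by default) ------------------------
    def drop_zero_rows(self) -> "CountMatrix":
        """Return a copy without entities that have zero counts everywhere."""
        keep = np.flatnonzero(self.row_totals > 0)
        if keep.size == 0:
            raise ValueError("all entities have zero counts")
        return self._take_rows(keep)

    def dedupe_rows(self) -> "CountMatrix":
        """Return a copy keeping only the first of each set of identical rows."""
        _, first = np.unique(self.counts, axis=0, return_index=True)
        keep = np.sort(first)
        return self._take_rows(keep)

    def _take_rows(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[idx],
            entity_ids=[self.entity_ids[i] for i in idx],
            condition_ids=self.condition_ids,
            column_totals=self.column_totals,
        )


@dataclass(frozen=True)
class PriorSpec:
    """Per-cell Beta prior parameters produced by one of the named schemes."""

    scheme: str
    alpha0: np.ndarray
    beta0: np.ndarray

    def __post_init__(self):
        if self.scheme not in PRIOR_SCHEMES:
            raise ValueError(
                f"unknown prior scheme {self.scheme!r}; expected one of {PRIOR_SCHEMES}")
        if self.alpha0.shape != self.beta0.shape:
            raise ValueError("alpha0 and beta0 shapes differ")
        if np.any(self.alpha0 <= 0) or np.any(self.beta0 <= 0):
            raise ValueError("Beta prior parameters must be strictly positive")

    @property
    def shape(self):
        return self.alpha0.shape


def make_prior(R: CountMatrix, scheme: str) -> PriorSpec:
    """Build the Beta prior parameters for ``scheme`` on count matrix ``R``.

    See the module docstring for the three schemes.  ``dirichlet_marginal``
    requires at least two entities (with m = 1 the marginal degenerates).
    """
    shape = (R.m, R.k)
    if scheme == "uniform":
        a0 = np.ones(shape)
        b0 = np.ones(shape)
    elif scheme == "dirichlet_marginal":
        if R.m < 2:
            raise ValueError("dirichlet_marginal prior requires at least 2 entities")
        a0 = np.full(shape, 1.0 / R.m)
        b0 = np.full(shape, 1.0 - 1.0 / R.m)
    elif scheme == "zero_count":
        a0 = np.broadcast_to(
            (R.column_totals + 1.0) / (R.r_max + 1.0), shape).copy()
        b0 = np.ones(shape)
    else:
        raise ValueError(
            f"unknown prior scheme {scheme!r}; expected one of {PRIOR_SCHEMES}")
    return PriorSpec(scheme=scheme, alpha0=a0, beta0=b0)


@dataclass(frozen=True)
class BeliefMatrices:
    """Posterior Beta parameters and their moments for every cell.

    Attributes
    ----------
    alpha, beta
        Posterior parameters ``a0 + R`` and ``b0 + R_c - R``.
    post_mean
        ``E(p_ic | c) = alpha / (alpha + beta)``.
    post_var
        ``Var(p_ic | c) = alpha*beta / ((alpha+beta)^2 (alpha+beta+1))`` —
        strictly positive, which is what keeps the Bayesian correlation
        denominator away from zero even for constant rows.
    row_mean
        ``E(p_ic) = (1/k) sum_c E(p_ic | c)``, the cross-condition average
        treating the condition as uniform on its k values.
    count_term
        The data part of the posterior mean, ``R_ic / (a0 + b0 + R_c)``.
        For the ``zero_count`` scheme the remaining prior part is constant
        across conditions (``1/(2 + R_max)``), so centering ``count_term``
        is algebraically identical to centering ``post_mean`` — and makes
        the all-zero-row correlations vanish exactly in floating point.
    scheme
        Name of the prior scheme the belief was computed under.
    """

    alpha: np.ndarray
    beta: np.ndarray
    post_mean: np.ndarray
    post_var: np.ndarray
    row_mean: np.ndarray
    count_term: np.ndarray
    scheme: str

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def k(self) -> int:
        return self.alpha.shape[1]


def compute_posterior(R: CountMatrix, prior: PriorSpec) -> BeliefMatrices:
    """Update the Beta prior with the observed counts (conjugate update).

    Raises if the prior shape does not match the matrix or if any condition
    has zero total counts (see :meth:`CountMatrix.require_positive_depths`).
    """
    if prior.shape != (R.m, R.k):
        raise ValueError(
            f"prior shape {prior.shape} does not match count matrix {(R.m, R.k)}")
    R.require_positive_depths()

    denom = prior.alpha0 + prior.beta0 + R.column_totals[None, :]
    alpha = prior.alpha0 + R.counts
    beta = prior.beta0 + R.column_totals[None, :] - R.counts
    post_mean = alpha / (alpha + beta)
    post_var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1.0))
    row_mean = post_mean.mean(axis=1)
    count_term = R.counts / denom
    return BeliefMatrices(
        alpha=alpha,
        beta=beta,
        post_mean=post_mean,
        post_var=post_var,
        row_mean=row_mean,
        count_term=count_term,
        scheme=prior.scheme,
    )
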