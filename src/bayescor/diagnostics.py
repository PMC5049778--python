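"""Analytical diagnostics for the Bayesian correlation estimator.

Three tools, usable both as user-facing QC and as independent checks:

* :func:`mean_abs_ratio_profile` — per-entity ratio of mean absolute
  Bayesian to mean absolute Pearson correlation, ordered by total read
  count.  A ratio well below 1 for low-count entities is the expected
  shrinkage signature; ratios above 1 at the low end flag the uniform-prior
  bias.
* :func:`zero_count_prior1_approx` — closed-form approximation to the
  uniform-prior correlation shared by any two entities with all-zero rows.
  It depends only on the depth profile: heterogeneous depths produce a
  spurious positive value, equal depths give exactly zero.
* :func:`theorem1_bound` — explicit upper bound on the magnitude of the
  zero-count-prior correlation of a sparse pair, in terms of the pair's
  maximum counts, the depth extremes, and how the conditions split by the
  pair's zero pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationResult
from .count_model import CountMatrix

__all__ = [
    "PairPartition",
    "pair_partition",
    "mean_abs_ratio_profile",
    "zero_count_prior1_approx",
    "theorem1_bound",
]


@dataclass(frozen=True)
class PairPartition:
    """Split of the k conditions by the zero pattern of an entity pair.

    ``k1``: entity i zero, entity j positive; ``k2``: i positive, j zero;
    ``k3``: both zero; ``k4``: both positive.  ``n_i``/``n_j`` are the
    largest single-condition counts of each row (zero iff the row is
    all-zero).
    """

    k1: int
    k2: int
    k3: int
    k4: int
    n_i: float
    n_j: float

    @property
    def k(self) -> int:
        return self.k1 + self.k2 + self.k3 + self.k4


def pair_partition(R: CountMatrix, i: int, j: int) -> PairPartition:
    """Classify every condition by whether entities ``i`` and ``j`` have counts."""
    ri, rj = R.counts[i], R.counts[j]
    zi, zj = ri == 0, rj == 0
    return PairPartition(
        k1=int(np.sum(zi & ~zj)),
        k2=int(np.sum(~zi & zj)),
        k3=int(np.sum(zi & zj)),
        k4=int(np.sum(~zi & ~zj)),
        n_i=float(ri.max()),
        n_j=float(rj.max()),
    )


def mean_abs_ratio_profile(
    bayes: CorrelationResult,
    pearson: CorrelationResult,
    R: CountMatrix,
) -> pd.DataFrame:
    """Per-entity mean |Bayesian| / mean |Pearson| correlation, by expression.

    For each entity the mean absolute correlation with all other entities is
    computed under both methods and their ratio reported, with entities
    ordered by increasing total read count.  Undefined Pearson entries
    (degenerate rows) are skipped in the Pearson average; an entity whose
    Pearson correlations are all undefined gets a NaN ratio.

    Returns a DataFrame with columns ``entity_id``, ``total_count``,
    ``ratio``.
    """
    if bayes.entity_ids != pearson.entity_ids or bayes.entity_ids != R.entity_ids:
        raise ValueError("entity sets of the two results and the counts differ")
    m = R.m
    if m < 2:
        raise ValueError("need at least two entities for cross-entity ratios")

    B = np.abs(bayes.matrix).astype(float).copy()
    P = np.abs(pearson.matrix).astype(float).copy()
    np.fill_diagonal(B, np.nan)
    np.fill_diagonal(P, np.nan)
    with np.errstate(invalid="ignore"):
        mean_b = np.nanmean(B, axis=1)
        # a row may be all-NaN in the Pearson matrix
        defined = np.sum(~np.isnan(P), axis=1)
        mean_p = np.where(defined > 0, np.nansum(P, axis=1) / np.maximum(defined, 1), np.nan)
        ratio = mean_b / mean_p

    order = np.argsort(R.row_totals, kind="stable")
    return pd.DataFrame(
        {
            "entity_id": [R.entity_ids[i] for i in order],
            "total_count": R.row_totals[order],
            "ratio": ratio[order],
        }
    ).reset_index(drop=True)


def zero_count_prior1_approx(column_totals) -> float:
    """Approximate uniform-prior correlation of two all-zero entities.

    For entities with no counts anywhere, the uniform prior leaves a
    posterior mean of roughly ``1/R_c`` per condition, so any two such
    entities share the same depth-driven profile.  Dropping the +2 prior
    offsets, their correlation is approximately

        var(1/R_c) / ( mean(1/R_c^2) + var(1/R_c) )

    with population (1/k) normalization.  Equal depths give exactly 0;
    heterogeneous depths give a strictly positive spurious correlation.
    """
    d = np.asarray(column_totals, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least two condition depths")
    if np.any(d <= 0):
        raise ValueError("all depths must be positive")
    inv = 1.0 / d
    num = np.mean((inv - inv.mean()) ** 2)
    den = np.mean(inv**2) + num
    return float(num / den)


def theorem1_bound(R: CountMatrix, i: int, j: int) -> float:
    """Upper bound on |r| under the zero-count prior for a sparse pair.

    Evaluates

        n_i * n_j * 4 R_max^2 / (k R_min^2) * (k1/k + k2/k + k3/k^2 + k4)

    from the zero-pattern partition of the pair.  Returns 0 when both rows
    are all-zero (the correlation itself is exactly zero then).  The bound
    is small when the pair's per-condition counts are small and counts are
    zero under most conditions, which is precisely the provable-suppression
    guarantee of the zero-count prior.
    """
    if i == j:
        raise ValueError("the bound is defined for distinct entities")
    part = pair_partition(R, i, j)
    if part.n_i == 0 and part.n_j == 0:
        return 0.0
    if R.r_min <= 0:
        raise ValueError("bound requires positive depth in every condition")
    k = R.k
    shape = part.k1 / k + part.k2 / k + part.k3 / k**2 + part.k4
    return float(part.n_i * part.n_j * 4.0 * R.r_max**2 / (k * R.r_min**2) * shape)
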