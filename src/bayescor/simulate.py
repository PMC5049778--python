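"""Synthetic count data: reference toys, binomial sampling, replicate resampling.

Everything the test-bench needs is generated here rather than downloaded:

* :func:`toy_fixtures` returns the two tiny reference matrices with their
  known correlation values — three genes at equal depth whose naive Pearson
  correlations are all 1, and two duplicated-profile pairs measured at very
  different depths.
* :func:`simulate_counts` draws count matrices from the generative model the
  estimator assumes: each cell independently ``Binomial(depth_c, p_ic)``.
* :func:`resample_replicates` emulates technical replication by multinomial
  resampling of each condition's reads at its own depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_model import CountMatrix

__all__ = [
    "ToyFixture",
    "SimSpec",
    "toy_fixtures",
    "paper_toys",
    "simulate_counts",
    "resample_replicates",
]


@dataclass(frozen=True)
class ToyFixture:
    """A named tiny count matrix with its expected correlation values.

    ``expected`` maps ``((id_a, id_b), method, prior_scheme)`` to the
    reference correlation value (3 decimals for the Bayesian entries);
    ``prior_scheme`` is ``None`` for classical methods.
    """

    name: str
    matrix: CountMatrix
    expected: dict


@dataclass(frozen=True)
class SimSpec:
    """Specification of a binomial count simulation.

    ``true_fractions`` is an m x k matrix of latent read fractions
    ``p_ic`` in [0, 1]; each column's fractions may sum to at most 1 (the
    remainder is unattributed sequencing output).  ``depths`` are the k
    per-condition totals, and ``seed`` makes the draw reproducible.
    """

    m: int
    k: int
    depths: np.ndarray
    true_fractions: np.ndarray
    seed: int

    def __post_init__(self):
        depths = np.asarray(self.depths)
        fr = np.asarray(self.true_fractions, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "true_fractions", fr)
        if depths.shape != (self.k,):
            raise ValueError("depths must have length k")
        if np.any(depths <= 0):
            raise ValueError("depths must be positive")
        if fr.shape != (self.m, self.k):
            raise ValueError("true_fractions must be m x k")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("true fractions must lie in [0, 1]")
        if np.any(fr.sum(axis=0) > 1 + 1e-12):
            raise ValueError("per-condition true fractions must sum to at most 1")


def toy_fixtures() -> list[ToyFixture]:
    """The two reference toy matrices with their known correlation values.

    ``equal_depth_trio``: genes x=(1000, 1000, 10000), y=(100, 100, 200),
    z=(0, 0, 1) at depth 10^6 in all three conditions.  All naive Pearson
    correlations are exactly 1; the uniform-prior Bayesian correlations are
    0.971 (x,y), 0.378 (x,z) and 0.367 (y,z) — shrunk according to how
    precisely each pair is measured.

    ``depth_contrast_pairs``: w = x = (10, 0, 0) and y = z = (0, 100, 0) at
    depths (10^6, 10^7, 10^6).  Pearson gives 1 for both duplicated pairs;
    the uniform-prior Bayesian correlations are 0.859 (w,x) and 0.948 (y,z),
    the second pair higher because its evidence sits in the deeper condition.

    Row sums are far below the stated depths because each toy is a small
    window into a larger transcriptome, so the depths are stored explicitly.
    """
    fixture1 = ToyFixture(
        name="equal_depth_trio",
        matrix=CountMatrix(
            [[1000, 1000, 10000], [100, 100, 200], [0, 0, 1]],
            entity_ids=("x", "y", "z"),
            condition_ids=("c1", "c2", "c3"),
            column_totals=[1e6, 1e6, 1e6],
        ),
        expected={
            (("x", "y"), "bayes", "uniform"): 0.971,
            (("x", "z"), "bayes", "uniform"): 0.378,
            (("y", "z"), "bayes", "uniform"): 0.367,
            (("x", "y"), "pearson", None): 1.0,
            (("x", "z"), "pearson", None): 1.0,
            (("y", "z"), "pearson", None): 1.0,
        },
    )
    fixture2 = ToyFixture(
        name="depth_contrast_pairs",
        matrix=CountMatrix(
            [[10, 0, 0], [10, 0, 0], [0, 100, 0], [0, 100, 0]],
            entity_ids=("w", "x", "y", "z"),
            condition_ids=("c1", "c2", "c3"),
            column_totals=[1e6, 1e7, 1e6],
        ),
        expected={
            (("w", "x"), "bayes", "uniform"): 0.859,
            (("y", "z"), "bayes", "uniform"): 0.948,
            (("w", "x"), "pearson", None): 1.0,
            (("y", "z"), "pearson", None): 1.0,
        },
    )
    return [fixture1, fixture2]


# Alias kept for discoverability: these are the worked reference examples.
paper_toys = toy_fixtures


def simulate_counts(spec: SimSpec) -> CountMatrix:
    """Draw a count matrix from the binomial sampling model.

    Every cell is an independent ``Binomial(depths[c], true_fractions[i, c])``
    draw under ``numpy``'s seeded default generator; the stated depths are
    stored as the matrix's column totals.
    """
    rng = np.random.default_rng(spec.seed)
    depths = np.asarray(spec.depths, dtype=np.int64)
    counts = rng.binomial(depths[None, :], spec.true_fractions)
    return CountMatrix(
        counts.astype(float),
        entity_ids=[f"sim_{i + 1}" for i in range(spec.m)],
        condition_ids=[f"cond_{c + 1}" for c in range(spec.k)],
        column_totals=depths.astype(float),
    )


def resample_replicates(R: CountMatrix, copies: int, seed: int) -> CountMatrix:
    """Append multinomially resampled pseudo-replicates of every condition.

    For each original condition, ``copies`` new columns are drawn by
    resampling its attributed reads with replacement: a multinomial over the
    entities with probabilities equal to the condition's empirical fractions
    and total equal to the condition's attributed read total (so each
    resampled column conserves its source's total exactly).  Original
    columns come first, then the resampled batches in order.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    totals = R.counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot resample a condition with zero attributed reads")
    rng = np.random.default_rng(seed)
    probs = R.counts / totals[None, :]

    new_cols = []
    new_ids = []
    for t in range(copies):
        for c in range(R.k):
            draw = rng.multinomial(int(round(totals[c])), probs[:, c])
            new_cols.append(draw.astype(float))
            new_ids.append(f"{R.condition_ids[c]}_rs{t + 1}")
    combined = np.column_stack([R.counts] + [col[:, None] for col in new_cols])
    new_totals = np.concatenate(
        [R.column_totals, [col.sum() for col in new_cols]])
    return CountMatrix(
        combined,
        entity_ids=R.entity_ids,
        condition_ids=list(R.condition_ids) + new_ids,
        column_totals=new_totals,
    )
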