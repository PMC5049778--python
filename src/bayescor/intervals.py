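"""Exact binomial plausible intervals for single count measurements.

A single cell of the count matrix is modeled as ``R_ic ~ Binomial(R_c, T/R_c)``
where ``T`` is the unknown true expected count.  The *plausible interval* at
level ``level`` is the set of hypothesized ``T`` values not rejected by the
exact two-sided binomial test, where the two-sided p-value at ``T`` sums the
probabilities of all outcomes no more probable than the observed one.  The
width of this interval, relative to the observed count, is a direct
frequentist read-out of measurement precision: one read out of a million is
compatible with true levels spanning two orders of magnitude, while 10^5
reads out of a million pin the true level to about a percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "PlausibleInterval",
    "binomial_two_sided_pvalue",
    "plausible_interval",
]


@dataclass(frozen=True)
class PlausibleInterval:
    """Non-rejected range of true expected counts for one measurement.

    ``t_low``/``t_high`` bracket the hypothesized expected counts ``T`` (on
    the count scale, not the fraction scale) that survive the exact
    two-sided binomial test at ``level``.  ``rel_uncertainty`` is the
    interval width as a percentage of the observed count (NaN when the
    observed count is zero).
    """

    observed: int
    depth: int
    level: float
    t_low: float
    t_high: float
    rel_uncertainty: float

    @property
    def width(self) -> float:
        return self.t_high - self.t_low


def _validate(observed: int, depth: int) -> tuple[int, int]:
    obs = int(observed)
    dep = int(depth)
    if obs != observed or dep != depth:
        raise ValueError("observed and depth must be integer counts")
    if dep <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= obs <= dep:
        raise ValueError("observed must lie in [0, depth]")
    return obs, dep


def binomial_two_sided_pvalue(observed: int, depth: int, T: float) -> float:
    """Exact two-sided binomial p-value for expected-count hypothesis ``T``.

    Under ``Binomial(depth, T/depth)``, sums the probabilities of every
    outcome whose probability is less than or equal to that of ``observed``
    (the observed outcome always contributes).  Equals 1 when ``observed``
    is the most probable outcome.
    """
    obs, dep = _validate(observed, depth)
    if not 0 < T < dep:
        raise ValueError("hypothesized expected count T must satisfy 0 < T < depth")
    return float(binomtest(obs, dep, T / dep, alternative="two-sided").pvalue)


def _bisect_boundary(pval, lo: float, hi: float, tol: float, accept_low: bool) -> float:
    """Locate the edge of {T : pval(T) >= level-indicator} by bisection.

    ``pval`` is the indicator function T -> (p-value >= level).  The bracket
    must satisfy indicator(hi side) != indicator(lo side); the returned point
    is on the accepting side of the boundary, within ``tol``.
    """
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pval(mid):
            if accept_low:
                hi = mid
            else:
                lo = mid
        else:
            if accept_low:
                lo = mid
            else:
                hi = mid
    return hi if accept_low else lo


def plausible_interval(
    observed: int,
    depth: int,
    level: float = 0.05,
    tol: float = 1e-4,
) -> PlausibleInterval:
    """Exact-test plausible interval for the true expected count.

    ``t_low`` is the smallest and ``t_high`` the largest hypothesized
    expected count with two-sided p-value >= ``level``, each located by
    bisection to absolute tolerance ``tol`` on the count scale (brackets are
    found by geometric expansion away from the observed count).  For an
    observed count of zero the lower endpoint is pinned at ``tol`` (any
    arbitrarily small positive level is plausible) and only the upper
    endpoint is searched.

    The p-value is piecewise continuous in ``T`` with small jumps where the
    set of "at most as probable" outcomes changes; bisection on the
    acceptance indicator locates the crossing regardless.
    """
    obs, dep = _validate(observed, depth)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")

    def accepted(T: float) -> bool:
        return binomial_two_sided_pvalue(obs, dep, T) >= level

    # Lower endpoint.
    if obs == 0:
        t_low = tol
    else:
        hi = float(obs)
        if not accepted(hi):  # pragma: no cover - obs is essentially the mode
            raise RuntimeError("observed count itself rejected; level too high?")
        lo = hi
        while accepted(lo):
            lo /= 2.0
            if lo < tol:
                lo = tol
                break
        if accepted(lo):
            t_low = lo
        else:
            t_low = _bisect_boundary(accepted, lo, hi, tol, accept_low=True)

    # Upper endpoint.
    lo = float(obs) if obs > 0 else tol
    hi = lo
    while accepted(hi):
        hi = min(hi * 2.0, dep - tol)
        if hi >= dep - tol:
            break
    if accepted(hi):
        t_high = hi
    else:
        t_high = _bisect_boundary(accepted, lo, hi, tol, accept_low=False)

    rel = (t_high - t_low) / obs * 100.0 if obs > 0 else float("nan")
    return PlausibleInterval(
        observed=obs,
        depth=dep,
        level=level,
        t_low=t_low,
        t_high=t_high,
        rel_uncertainty=rel,
    )
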