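"""Cost ratios, ratio ranges and the linear-programming parsimony filter.

Parsimonious reconciliations depend only on the *ratios* between the event
costs, so a cost vector c = (delta, tau, lambda) is summarized by its ratio
vector r(c) = (lambda/tau, delta/tau, lambda/delta).  Given a box of admissible
ratios, a Pareto-optimal count vector is *parsimonious within the range* iff
there is at least one admissible cost vector for which it attains the minimum
total cost.  After normalizing tau = 1 this is a two-variable linear
feasibility problem in (delta, lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .pareto import ParetoList, Vector, pareto_filter

__all__ = ["CostVector", "RatioRange", "ratio_of", "range_around",
           "range_from_bounds", "compute_pars", "costs_from_frequencies"]

_POS = 1e-9  # stand-in lower bound for "strictly positive" in the LP
_TOL = 1e-9


class CostVector(NamedTuple):
    """Costs of a duplication, a transfer and a loss (all strictly positive)."""

    delta: float
    tau: float
    lam: float

    @staticmethod
    def make(costs: Sequence[float]) -> "CostVector":
        c = CostVector(*map(float, costs))
        if any(v <= 0 for v in c):
            raise ValueError(f"cost components must be strictly positive: {c}")
        return c


def ratio_of(costs: Sequence[float]) -> Tuple[float, float, float]:
    """Ratio cost vector (lambda/tau, delta/tau, lambda/delta)."""
    delta, tau, lam = CostVector.make(costs)
    return (lam / tau, delta / tau, lam / delta)


@dataclass(frozen=True)
class RatioRange:
    """Componentwise bounds on (lambda/tau, delta/tau, lambda/delta).

    Components of ``r_m`` may be 0 and components of ``r_M`` may be +inf for
    unconstrained directions.
    """

    r_m: Tuple[float, float, float]
    r_M: Tuple[float, float, float]

    def __post_init__(self):
        for lo, hi in zip(self.r_m, self.r_M):
            if math.isnan(lo) or math.isnan(hi) or lo < 0 or hi < lo:
                raise ValueError(f"invalid ratio range [{self.r_m}; {self.r_M}]")

    @staticmethod
    def free() -> "RatioRange":
        """The full positive orthant (no ratio constraints)."""
        return RatioRange((0.0, 0.0, 0.0), (math.inf, math.inf, math.inf))

    @staticmethod
    def point(costs: Sequence[float]) -> "RatioRange":
        """Degenerate range pinned at the ratios of one cost vector."""
        r = ratio_of(costs)
        return RatioRange(r, r)


def range_around(costs: Sequence[float], pct_dt: float,
                 pct_ld: float) -> RatioRange:
    """Ratio box around r(c), varying delta/tau and lambda/delta by +-pct.

    The lambda/tau bounds are the products of the corresponding extreme bounds
    of the two varied ratios (lambda/tau = (delta/tau) * (lambda/delta)).
    """
    for pct in (pct_dt, pct_ld):
        if not 0 <= pct < 100:
            raise ValueError(f"percentage must be in [0, 100): {pct}")
    lt, dt, ld = ratio_of(costs)
    f_dt = (1 - pct_dt / 100.0, 1 + pct_dt / 100.0)
    f_ld = (1 - pct_ld / 100.0, 1 + pct_ld / 100.0)
    r_m = (f_dt[0] * f_ld[0] * lt, f_dt[0] * dt, f_ld[0] * ld)
    r_M = (f_dt[1] * f_ld[1] * lt, f_dt[1] * dt, f_ld[1] * ld)
    return RatioRange(r_m, r_M)


def range_from_bounds(lambda_delta: Tuple[float, float],
                      tau_delta: Tuple[float, float]) -> RatioRange:
    """Ratio box implied by bounds on lambda/delta and tau/delta.

    With lambda/delta in [a, b] and tau/delta in [p, q]:
    lambda/tau in [a/q, b/p] and delta/tau in [1/q, 1/p].
    """
    a, b = lambda_delta
    p, q = tau_delta
    if a <= 0 or p <= 0 or b < a or q < p:
        raise ValueError("bounds must be positive with lower <= upper")
    return RatioRange((a / q, 1.0 / q, a), (b / p, 1.0 / p, b))


def compute_pars(front: Sequence[Vector], ratio_range: RatioRange) -> ParetoList:
    """Filter a Pareto front to the vectors parsimonious within a ratio range.

    With tau normalized to 1 the ratio vector is (lambda, delta, lambda/delta).
    A vector v is retained iff the linear system

        v . (delta, 1, lambda) <= v' . (delta, 1, lambda)   for all v' != v

    has a solution (delta, lambda) with r_m <= (lambda, delta, lambda/delta)
    <= r_M (the lambda/delta bounds rewritten linearly).  Ties are allowed:
    parsimony means attaining the minimum, not being its unique witness.
    """
    front = pareto_filter(front)
    if not front:
        raise ValueError("empty Pareto front")
    lt_lo, dt_lo, ld_lo = ratio_range.r_m
    lt_hi, dt_hi, ld_hi = ratio_range.r_M

    # variable order: (delta, lambda)
    delta_bounds = (max(dt_lo, _POS), None if math.isinf(dt_hi) else dt_hi)
    lam_bounds = (max(lt_lo, _POS), None if math.isinf(lt_hi) else lt_hi)

    base_A: list = []
    base_b: list = []
    if ld_lo > 0:  # lambda/delta >= ld_lo  <=>  ld_lo * delta - lambda <= 0
        base_A.append([ld_lo, -1.0])
        base_b.append(0.0)
    if not math.isinf(ld_hi):  # lambda <= ld_hi * delta
        base_A.append([-ld_hi, 1.0])
        base_b.append(0.0)

    retained = []
    for v in front:
        A = list(base_A)
        b = list(base_b)
        for w in front:
            if w == v:
                continue
            # (dv - dw) delta + (lv - lw) lambda <= (tw - tv)
            A.append([v[0] - w[0], v[2] - w[2]])
            b.append(float(w[1] - v[1]) + _TOL)
        res = linprog(c=[0.0, 0.0],
                      A_ub=np.array(A) if A else None,
                      b_ub=np.array(b) if b else None,
                      bounds=[delta_bounds, lam_bounds], method="highs")
        if res.status == 0:
            retained.append(v)
    return tuple(retained)


def costs_from_frequencies(n_d: float, n_t: float, n_l: float,
                           base: Optional[float] = None) -> CostVector:
    """Cost vector from observed event counts: cost(e) = log(n_tot / n_e).

    Rare events become expensive.  The logarithm is natural by default;
    ``base`` overrides it.  Zero counts are rejected (the cost is undefined
    and the event would otherwise be free).
    """
    counts = (n_d, n_t, n_l)
    if any(n <= 0 for n in counts):
        raise ValueError("all event counts must be positive")
    n_tot = sum(counts)
    logs = [math.log(n_tot / n) for n in counts]
    if base is not None:
        logs = [v / math.log(base) for v in logs]
    return CostVector.make(logs)
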