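"""Pareto-list algebra on (duplication, transfer, loss) count vectors.

A Pareto list is the canonical representation of a Pareto front: the vectors
are mutually incomparable under the componentwise order, duplicate-free and
lexicographically sorted, so two fronts are equal iff the tuples are equal.
These lists are the currency of the reconciliation dynamic program.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

Vector = Tuple[int, int, int]
ParetoList = Tuple[Vector, ...]

__all__ = ["pareto_filter", "oplus_p", "concat_pareto", "add_vector",
           "is_pareto_list", "dominated"]


def dominated(v: Vector, w: Vector) -> bool:
    """True iff w <= v componentwise and w != v (w strictly dominates v)."""
    return w != v and w[0] <= v[0] and w[1] <= v[1] and w[2] <= v[2]


def pareto_filter(vectors: Iterable[Vector]) -> ParetoList:
    """Keep exactly the vectors not strictly dominated by another input vector.

    Deduplicates and sorts.  A dominating vector is always lexicographically
    smaller than the vector it dominates, so a single sorted sweep against the
    kept staircase suffices.
    """
    vs = sorted(set(vectors))
    kept: list = []
    for v in vs:
        if not any(w[0] <= v[0] and w[1] <= v[1] and w[2] <= v[2] for w in kept):
            kept.append(v)
    return tuple(kept)


def oplus_p(l1: Sequence[Vector], l2: Sequence[Vector]) -> ParetoList:
    """Pareto filter of all pairwise sums {v1 + v2 : v1 in l1, v2 in l2}.

    Empty when either operand is empty (an impossible sub-solution propagates).
    """
    if not l1 or not l2:
        return ()
    sums = {
        (a[0] + b[0], a[1] + b[1], a[2] + b[2])
        for a in l1
        for b in l2
    }
    return pareto_filter(sums)


def concat_pareto(*lists: Sequence[Vector]) -> ParetoList:
    """Pareto filter of the union of the given lists."""
    union: set = set()
    for l in lists:
        union.update(l)
    return pareto_filter(union)


def add_vector(v: Vector, l: Sequence[Vector]) -> ParetoList:
    """Translate every vector of a Pareto list by v (stays a Pareto list)."""
    return tuple((v[0] + a[0], v[1] + a[1], v[2] + a[2]) for a in l)


def is_pareto_list(l: Sequence[Vector]) -> bool:
    """Structural check: sorted, unique, mutually incomparable."""
    if list(l) != sorted(set(l)):
        return False
    for i, v in enumerate(l):
        for j, w in enumerate(l):
            if i != j and dominated(v, w):
                return False
    return True
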