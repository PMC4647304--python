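"""The Pareto-front reconciliation dynamic program.

For every gene node u and subdivided-species node x, ``C(u, x)`` is the Pareto
list of event count vectors achievable by reconciliations of the gene subtree
at u whose first mapping is x.  The recursion follows the postlist clauses,
processing gene nodes bottom-up and S' nodes in increasing time order.  Within
a time slice the computation is two-phased: first the TL-free lists (phase 1),
then the TL contributions, which must draw on the TL-free lists of co-timed
nodes because consecutive TL events are forbidden.

Two modes are supported:

* ``pareto`` — plain Pareto fronts; the root front collects every vector of a
  Pareto-optimal reconciliation.
* ``epsilon`` — every per-mapping list is additionally pruned to vectors whose
  cost (for a given cost vector) is within an over-cost ``epsilon`` of the
  per-mapping minimum; the root front is then exactly the set of
  epsilon-Pareto-optimal vectors (Pareto-optimal and within ``epsilon`` of the
  global minimum).  Closure under restriction makes the local pruning sound.

A scalar (min, +) variant of the same recursion computes minimum costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .pareto import (ParetoList, Vector, add_vector, concat_pareto, oplus_p,
                     pareto_filter)
from .trees import GeneTree, SubdividedTree
from . import events as ev

__all__ = ["DPOptions", "ParetoMatrix", "compute_pareto_matrix", "best_triplets",
           "min_cost", "epsilon_star_filter"]

_TOL = 1e-9

V_D = ev.event_vector(ev.D)
V_T = ev.event_vector(ev.T)
V_SL = ev.event_vector(ev.SL)
V_TL = ev.event_vector(ev.TL)


@dataclass
class DPOptions:
    """Options of the reconciliation DP.

    mode: ``"pareto"`` (cost-free fronts) or ``"epsilon"`` (cost-pruned).
    costs: (delta, tau, lambda) — required in epsilon mode.
    epsilon: allowed over-cost above the minimum (epsilon mode).
    star_filter: additionally prune every list with the transfer-chain filter
        (see :func:`epsilon_star_filter`); an optimization that must leave the
        root front unchanged relative to filtering the root list only.
    """

    mode: str = "pareto"
    costs: Optional[Tuple[float, float, float]] = None
    epsilon: float = 0.0
    star_filter: bool = False

    def __post_init__(self):
        if self.mode not in ("pareto", "epsilon"):
            raise ValueError(f"unknown DP mode {self.mode!r}")
        if self.mode == "epsilon":
            if self.costs is None:
                raise ValueError("epsilon mode requires a cost vector")
            if any(c <= 0 for c in self.costs):
                raise ValueError("event costs must be strictly positive")
            if self.epsilon < 0:
                raise ValueError("the over-cost epsilon must be >= 0")


@dataclass
class ParetoMatrix:
    """Per-mapping Pareto lists produced by the DP.

    ``final[u, x]`` is C(u, x); ``phase1[u, x]`` the TL-free list (needed both
    for the TL recursion and for the reconciliation-graph builder, which must
    never chain two TL events).  ``root_front`` is the Pareto front over all
    root placements — in epsilon mode already restricted to vectors within
    ``epsilon`` of the optimal cost.
    """

    gene_tree: GeneTree
    sp: SubdividedTree
    options: DPOptions
    final: Dict[Tuple[str, str], ParetoList] = field(default_factory=dict)
    phase1: Dict[Tuple[str, str], ParetoList] = field(default_factory=dict)
    root_front: ParetoList = ()
    min_cost_total: Optional[float] = None
    min_cost_table: Optional[Dict[Tuple[str, str], float]] = None

    def dump_rows(self):
        """Debug dump: rows (u, x, phase, d, t, l)."""
        rows = []
        for (u, x), lst in sorted(self.phase1.items()):
            rows.extend((u, x, "phase1", *v) for v in lst)
        for (u, x), lst in sorted(self.final.items()):
            rows.extend((u, x, "final", *v) for v in lst)
        return rows


def _slice_union(lists_by_node: Dict[str, ParetoList]) -> Dict[Vector, set]:
    """Map each vector to the set of slice nodes whose list contains it."""
    contrib: Dict[Vector, set] = {}
    for name, lst in lists_by_node.items():
        for v in lst:
            contrib.setdefault(v, set()).add(name)
    return contrib


def best_triplets(lists_by_node: Dict[str, ParetoList],
                  exclude: str) -> ParetoList:
    """Pareto front of the union of a slice's lists over nodes != exclude.

    Implemented with per-vector contributor sets so the per-node fronts are
    derived from one union pass; vectors contributed only by the excluded
    node are removed *before* filtering (removing them after would discard
    receiver options that the excluded node's own list dominates).
    """
    contrib = _slice_union(lists_by_node)
    cands = [v for v, who in contrib.items() if who != {exclude}]
    return pareto_filter(cands)


def epsilon_star_filter(vectors: Sequence[Vector]) -> ParetoList:
    """Drop vectors dominated in the transformed order (t, l, d+t).

    A vector (d, t, l) is removed iff some distinct (d', t', l') in the list
    has l' <= l, t' <= t and d' + t' <= d + t.  Such a vector can only be
    optimal when transfers are dramatically cheaper than duplications — the
    signature of spurious transfer-and-return chains.  Distinct vectors cannot
    weakly dominate each other both ways (that forces equality), so the result
    does not depend on processing order; the filter is a Pareto filter in the
    transformed coordinates.
    """
    vs = list(dict.fromkeys(vectors))
    kept = []
    for v in vs:
        d, t, l = v
        if not any(
            w != v and w[2] <= l and w[1] <= t and w[0] + w[1] <= d + t
            for w in vs
        ):
            kept.append(v)
    return tuple(sorted(kept))


# ---------------------------------------------------------------------------
# scalar (min, +) DP


def min_cost(gene_tree: GeneTree, sp: SubdividedTree,
             costs: Sequence[float]) -> Tuple[float, Dict[Tuple[str, str], float]]:
    """Minimum reconciliation cost and the per-mapping cost table.

    Same recursion as the Pareto DP on the (min, +) semiring; the table maps
    (gene node, S' node) to the cheapest reconciliation rooted there.
    """
    delta, tau, lam = costs
    if delta <= 0 or tau <= 0 or lam <= 0:
        raise ValueError("event costs must be strictly positive")
    INF = math.inf
    cost_f: Dict[Tuple[str, str], float] = {}
    gene_post = list(gene_tree.postorder())

    for t in sp.times:
        slice_nodes = sp.slices[t]
        for u in gene_post:
            p1: Dict[str, float] = {}
            for x in slice_nodes:
                best = INF
                if u.is_leaf and x.kind == "leaf" and x.species == u.species:
                    best = 0.0
                if x.kind == "artificial":
                    best = min(best, cost_f[u.name, x.children[0].name])
                if x.kind == "speciation":
                    x1, x2 = (c.name for c in x.children)
                    best = min(best, lam + cost_f[u.name, x1],
                               lam + cost_f[u.name, x2])
                    if not u.is_leaf:
                        u1, u2 = (c.name for c in u.children)
                        best = min(best,
                                   cost_f[u1, x1] + cost_f[u2, x2],
                                   cost_f[u1, x2] + cost_f[u2, x1])
                if not u.is_leaf:
                    u1, u2 = (c.name for c in u.children)
                    best = min(best, delta + cost_f[u1, x.name] + cost_f[u2, x.name])
                    for z in sp.co_timed(x):
                        best = min(best,
                                   tau + cost_f[u1, x.name] + cost_f[u2, z.name],
                                   tau + cost_f[u2, x.name] + cost_f[u1, z.name])
                p1[x.name] = best
            for x in slice_nodes:
                best = p1[x.name]
                for z in sp.co_timed(x):
                    best = min(best, tau + lam + p1[z.name])
                cost_f[u.name, x.name] = best

    root = gene_tree.root.name
    total = min(cost_f[root, x.name] for x in sp.postorder())
    return total, cost_f


# ---------------------------------------------------------------------------
# Pareto DP


def compute_pareto_matrix(gene_tree: GeneTree, sp: SubdividedTree,
                          options: Optional[DPOptions] = None) -> ParetoMatrix:
    """Fill the Pareto matrix C(u, x) for all gene nodes and S' nodes."""
    options = options or DPOptions()
    if not gene_tree.species_set <= sp.species_tree.species_set:
        raise ValueError("gene-tree species are not a subset of the species tree")

    eps_mode = options.mode == "epsilon"
    if eps_mode:
        total_min, cost_table = min_cost(gene_tree, sp, options.costs)
    else:
        total_min, cost_table = None, None

    matrix = ParetoMatrix(gene_tree, sp, options)
    matrix.min_cost_total = total_min
    matrix.min_cost_table = cost_table
    final, phase1 = matrix.final, matrix.phase1
    gene_post = list(gene_tree.postorder())

    def prune(lst: ParetoList, u: str, x: str) -> ParetoList:
        if eps_mode:
            limit = cost_table[u, x] + options.epsilon + _TOL
            lst = tuple(v for v in lst
                        if ev.cost_of(v, options.costs) <= limit)
        if options.star_filter:
            lst = epsilon_star_filter(lst)
        return lst

    for t in sp.times:
        slice_nodes = sp.slices[t]
        for u in gene_post:
            # phase 1: every event but TL
            for x in slice_nodes:
                parts: List[ParetoList] = []
                if u.is_leaf and x.kind == "leaf" and x.species == u.species:
                    parts.append(((0, 0, 0),))
                if x.kind == "artificial":
                    parts.append(final[u.name, x.children[0].name])
                if x.kind == "speciation":
                    x1, x2 = (c.name for c in x.children)
                    parts.append(add_vector(V_SL, final[u.name, x1]))
                    parts.append(add_vector(V_SL, final[u.name, x2]))
                    if not u.is_leaf:
                        u1, u2 = (c.name for c in u.children)
                        parts.append(oplus_p(final[u1, x1], final[u2, x2]))
                        parts.append(oplus_p(final[u1, x2], final[u2, x1]))
                if not u.is_leaf:
                    u1, u2 = (c.name for c in u.children)
                    parts.append(add_vector(
                        V_D, oplus_p(final[u1, x.name], final[u2, x.name])))
                    if len(slice_nodes) > 1:
                        by_node_1 = {z.name: final[u1, z.name] for z in slice_nodes}
                        by_node_2 = {z.name: final[u2, z.name] for z in slice_nodes}
                        bt2 = best_triplets(by_node_2, x.name)
                        bt1 = best_triplets(by_node_1, x.name)
                        parts.append(add_vector(
                            V_T, oplus_p(final[u1, x.name], bt2)))
                        parts.append(add_vector(
                            V_T, oplus_p(final[u2, x.name], bt1)))
                phase1[u.name, x.name] = prune(concat_pareto(*parts),
                                               u.name, x.name)
            # phase 2: TL, drawing on the TL-free lists of the slice
            p1_by_node = {x.name: phase1[u.name, x.name] for x in slice_nodes}
            for x in slice_nodes:
                lst = phase1[u.name, x.name]
                if len(slice_nodes) > 1:
                    bt0 = best_triplets(p1_by_node, x.name)
                    lst = concat_pareto(lst, add_vector(V_TL, bt0))
                final[u.name, x.name] = prune(lst, u.name, x.name)

    root = gene_tree.root.name
    front = concat_pareto(*(final[root, x.name] for x in sp.postorder()))
    if eps_mode:
        limit = total_min + options.epsilon + _TOL
        front = pareto_filter(
            v for v in front if ev.cost_of(v, options.costs) <= limit)
    if options.star_filter:
        front = epsilon_star_filter(front)
    matrix.root_front = front
    if not front:
        raise AssertionError(
            "empty root front: should be impossible for valid inputs")
    return matrix
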