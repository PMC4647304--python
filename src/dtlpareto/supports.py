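"""Counting traversals of the reconciliation graph, event supports and the
median reconciliation.

``score(z)`` counts the sub-solutions below a node (post-order: product over
an event node's children, sum over a mapping node's event children);
``recNum(z)`` counts the depicted reconciliations containing the node
(pre-order, splitting a parent's count proportionally to scores — always an
exact integer division).  The support f(e) of a species-located event is the
fraction of depicted reconciliations containing it, obtained by summing
recNum over the event nodes sharing its identity.

The median reconciliation minimizes the total symmetric event-set distance to
all depicted reconciliations; equivalently it maximizes the sum of
(2 f(e) - 1) over its events, a max-weight full subtree found by one more
graph traversal.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import events as ev
from .events import EventRecord, Reconciliation, atomic_records
from .recgraph import EventNode, MappingNode, ReconciliationGraph

__all__ = ["SupportTable", "compute_scores", "compute_recnum",
           "event_supports", "median_reconciliation", "filter_by_threshold"]


def _topo_order(graph: ReconciliationGraph) -> List[object]:
    """All nodes, parents before children (mapping and event nodes mixed)."""
    order: List[object] = []
    state: Dict[int, int] = {}

    def visit(node) -> None:
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            if done:
                order.append(n)
                state[id(n)] = 2
                continue
            if state.get(id(n)):
                continue
            state[id(n)] = 1
            stack.append((n, True))
            kids = n.events if isinstance(n, MappingNode) else n.children
            for k in kids:
                if not state.get(id(k)):
                    stack.append((k, False))

    for r in graph.roots:
        visit(r)
    order.reverse()
    return order


def compute_scores(graph: ReconciliationGraph) -> Dict[int, int]:
    """score(z): completable sub-solutions rooted at z, keyed by id(z)."""
    scores: Dict[int, int] = {}
    for node in reversed(_topo_order(graph)):
        if isinstance(node, EventNode):
            if node.etype == ev.C:
                scores[id(node)] = 1
            else:
                s = 1
                for c in node.children:
                    s *= scores[id(c)]
                scores[id(node)] = s
        else:
            scores[id(node)] = sum(scores[id(e)] for e in node.events)
    return scores


def compute_recnum(graph: ReconciliationGraph,
                   scores: Dict[int, int]) -> Dict[int, int]:
    """recNum(z): depicted reconciliations containing z, keyed by id(z)."""
    recnum: Dict[int, int] = {}
    root_ids = {id(r) for r in graph.roots}
    for node in _topo_order(graph):
        if isinstance(node, MappingNode):
            if id(node) in root_ids:
                recnum[id(node)] = scores[id(node)]
            else:
                recnum[id(node)] = sum(recnum[id(p)] for p in node.parents)
        else:
            p = node.parent
            num = recnum[id(p)] * scores[id(node)]
            den = scores[id(p)]
            q, r = divmod(num, den)
            if r:
                raise AssertionError("non-integer recNum: corrupted graph")
            recnum[id(node)] = q
    return recnum


@dataclass
class SupportTable:
    """Event supports over the depicted solution space.

    ``composite`` maps species-located composite events (S, D, T, SL, TL —
    keyed with their gene node) to exact fractional supports; ``atomic`` maps
    gene-anonymous atomic D/T/L records to their expected multiplicity per
    reconciliation (a sum of composite supports, which can exceed 1 when an
    atomic event recurs).  ``n_reconciliations`` is the size of the space.
    """

    composite: Dict[EventRecord, Fraction]
    atomic: Dict[EventRecord, Fraction]
    n_reconciliations: int

    def support(self, rec: EventRecord) -> Fraction:
        return self.composite[rec]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, f in sorted(self.composite.items()):
            rows.append({"event_type": rec.etype, "gene_node": rec.gene,
                         "location": "|".join(rec.loc),
                         "support": float(f), "kind": "composite"})
        for rec, f in sorted(self.atomic.items()):
            rows.append({"event_type": rec.etype, "gene_node": "",
                         "location": "|".join(rec.loc),
                         "support": float(f), "kind": "atomic"})
        return pd.DataFrame(
            rows, columns=["event_type", "gene_node", "location",
                           "support", "kind"])


def event_supports(graph: ReconciliationGraph,
                   recnum: Dict[int, int],
                   n_reconciliations: int,
                   include_neutral: bool = False) -> SupportTable:
    """Aggregate per-event-node frequencies into species-level supports.

    Placements of one event in different slices of a branch (and in different
    count-vector contexts) share an identity and their frequencies sum.  C and
    no-event crossings carry no duplication/transfer/loss content and are
    excluded unless ``include_neutral``.
    """
    if n_reconciliations <= 0:
        raise ValueError("empty solution space")
    composite: Dict[EventRecord, Fraction] = defaultdict(Fraction)
    for e in graph.event_nodes:
        if e.record is None:
            continue
        if e.etype == ev.C and not include_neutral:
            continue
        composite[e.record] += Fraction(recnum[id(e)], n_reconciliations)
    atomic: Dict[EventRecord, Fraction] = defaultdict(Fraction)
    st = graph.sp.species_tree
    for rec, f in composite.items():
        for a in atomic_records(rec, st):
            atomic[a] += f
    return SupportTable(dict(composite), dict(atomic), n_reconciliations)


def median_reconciliation(graph: ReconciliationGraph,
                          table: SupportTable) -> Reconciliation:
    """A depicted reconciliation minimizing the summed event distance.

    Runs a max-weight full-subtree DP with event weight 2 f(e) - 1 (neutral
    events weigh 0).  Ties broken deterministically by stored child order.
    """
    weights: Dict[int, Fraction] = {}
    for e in graph.event_nodes:
        if e.record is not None and e.etype != ev.C:
            weights[id(e)] = 2 * table.composite[e.record] - 1

    value: Dict[int, Fraction] = {}
    choice: Dict[int, EventNode] = {}
    for node in reversed(_topo_order(graph)):
        if isinstance(node, EventNode):
            v = weights.get(id(node), Fraction(0))
            for c in node.children:
                v += value[id(c)]
            value[id(node)] = v
        else:
            best, best_e = None, None
            for e in node.events:
                v = value[id(e)]
                if best is None or v > best:
                    best, best_e = v, e
            value[id(node)] = best
            choice[id(node)] = best_e

    root = max(graph.roots, key=lambda r: (value[id(r)],))
    # extract the chosen full subtree as a reconciliation
    mapping: Dict[str, List[str]] = {}
    stack: List[MappingNode] = [root]
    while stack:
        m = stack.pop()
        mapping.setdefault(m.u, []).append(m.x)
        e = choice[id(m)]
        if e.etype in (ev.EMPTY, ev.SL, ev.TL):
            stack.append(e.children[0])
        elif e.etype in ev.BIRTH_EVENTS:
            stack.extend(reversed(e.children))
    med = Reconciliation(mapping, graph.gene_tree, graph.sp)
    recs = med.records()
    if len(set(recs)) != len(recs):  # pragma: no cover - pathological
        warnings.warn("median reconciliation repeats an event identity; "
                      "its distance score treats occurrences independently")
    return med


def filter_by_threshold(median_records: Sequence[EventRecord],
                        table: SupportTable,
                        threshold: float) -> List[EventRecord]:
    """Events of the median reconciliation with support >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be within [0, 1]")
    return [r for r in median_records
            if table.composite.get(r, Fraction(0)) >= threshold]
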