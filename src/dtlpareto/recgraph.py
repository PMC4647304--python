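"""The reconciliation graph: a bipartite DAG of mapping and event nodes whose
full subtrees are exactly the canonical reconciliations with retained root
event count vectors.

A mapping node carries (gene node u, S' node x, count vector v) plus an *entry
tag* constraining the first event of u's sequence at x; an event node carries
an event type, has one mapping-node parent and conforming mapping-node
children, and satisfies v(parent) = v(event) + sum of the children vectors.

Entry tags serve two correlation constraints that a plain (u, x, v) node
cannot express:

* ``no_tl`` — the child of a TL event node must not itself start with a TL
  (consecutive TLs are forbidden by the model);
* canonical form — D, T and TL events whose S' endpoints are all artificial
  can be shifted one slice down whenever every lineage they spawn immediately
  crosses out of the slice; such placements are not canonical (the same
  species-level events exist one slice lower).  Event nodes for these
  "slidable" event types therefore partition their children into disjoint
  combinations that force at least one spawned lineage to start with a real
  event, whose own combinations recursively guarantee — in the same time
  slice — either a pinned event (one with a non-artificial endpoint) or a
  *blocked* TL, one whose continuation is a crossing followed immediately by
  another TL and hence cannot shift down without chaining two TLs.  Root
  sequences must not start with a no-event crossing for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import islice, product
from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Tuple

from . import events as ev
from .dp import ParetoMatrix
from .events import EventRecord, Reconciliation
from .pareto import Vector
from .trees import GeneTree, SpeciesNode, SubdividedTree

__all__ = ["MappingKey", "MappingNode", "EventNode", "ReconciliationGraph",
           "build_graph", "enumerate_full_subtrees", "count_reconciliations"]

# entry tags
ANY = "any"               # no constraint on the first event
NONEMPTY = "nonempty"     # first event must not be the no-event crossing
ONLYEMPTY = "onlyempty"   # first event must be the no-event crossing
ONLYEMPTY_TL = "empty+tl"  # forced crossing whose follow-up must be a TL
ONLYTL = "onlytl"         # first event must be a TL

_EVENT_ORDER = {e: i for i, e in enumerate(
    (ev.S, ev.D, ev.T, ev.SL, ev.TL, ev.EMPTY, ev.C))}


class MappingKey(NamedTuple):
    u: str
    x: str
    v: Vector
    entry: str
    no_tl: bool


@dataclass(eq=False)
class MappingNode:
    key: MappingKey
    events: List["EventNode"] = field(default_factory=list)
    parents: List["EventNode"] = field(default_factory=list)

    @property
    def u(self):
        return self.key.u

    @property
    def x(self):
        return self.key.x

    @property
    def v(self):
        return self.key.v

    def __repr__(self):  # pragma: no cover
        return f"<M {self.key.u}@{self.key.x} {self.key.v} {self.key.entry}>"


@dataclass(eq=False)
class EventNode:
    etype: str
    parent: Optional[MappingNode]
    children: Tuple[MappingNode, ...]
    receiver: Optional[str] = None      # S' node name of the T/TL receiver
    record: Optional[EventRecord] = None

    def __repr__(self):  # pragma: no cover
        return f"<E {self.etype} of {self.parent and self.parent.key}>"


@dataclass
class ReconciliationGraph:
    gene_tree: GeneTree
    sp: SubdividedTree
    roots: List[MappingNode]
    mapping_nodes: Dict[MappingKey, MappingNode]
    event_nodes: List[EventNode]

    def iter_mapping_nodes(self) -> Iterator[MappingNode]:
        return iter(self.mapping_nodes.values())

    def to_json(self) -> str:
        mids = {id(m): i for i, m in enumerate(self.mapping_nodes.values())}
        nodes = []
        for m in self.mapping_nodes.values():
            nodes.append({"id": mids[id(m)], "kind": "mapping",
                          "gene": m.u, "species": m.x, "vector": list(m.v),
                          "entry": m.key.entry, "no_tl": m.key.no_tl,
                          "root": m in self.roots})
        edges = []
        for j, e in enumerate(self.event_nodes):
            nid = len(mids) + j
            nodes.append({"id": nid, "kind": "event", "event": e.etype,
                          "receiver": e.receiver})
            edges.append([mids[id(e.parent)], nid])
            edges.extend([nid, mids[id(c)]] for c in e.children)
        return json.dumps({"nodes": nodes, "edges": edges}, indent=1)

    def to_dot(self) -> str:
        lines = ["digraph reconciliations {"]
        mids = {id(m): f"m{i}" for i, m in enumerate(self.mapping_nodes.values())}
        for m in self.mapping_nodes.values():
            shape = "doubleoctagon" if m in self.roots else "box"
            lines.append(
                f'  {mids[id(m)]} [shape={shape} label="{m.u},{m.x},{m.v}"];')
        for j, e in enumerate(self.event_nodes):
            lab = e.etype if not e.receiver else f"{e.etype}->{e.receiver}"
            lines.append(f'  e{j} [shape=circle label="{lab}"];')
            lines.append(f"  {mids[id(e.parent)]} -> e{j};")
            for c in e.children:
                lines.append(f"  e{j} -> {mids[id(c)]};")
        lines.append("}")
        return "\n".join(lines)

    # -- structural checks (used by the test suite) ------------------------

    def check_invariants(self) -> None:
        seen_keys = set()
        for key, m in self.mapping_nodes.items():
            assert key not in seen_keys
            seen_keys.add(key)
            gn = self.gene_tree.nodes[m.u]
            xn = self.sp.nodes[m.x]
            matched_leaf = (gn.is_leaf and xn.kind == "leaf"
                            and xn.species == gn.species and m.v == (0, 0, 0))
            assert m.events, f"mapping node without event children: {key}"
            if matched_leaf and m.key.entry != ONLYEMPTY:
                assert len(m.events) == 1 and m.events[0].etype == ev.C
            else:
                assert all(e.etype != ev.C for e in m.events)
        for e in self.event_nodes:
            assert e.parent is not None
            if e.etype == ev.C:
                assert not e.children
                continue
            total = list(ev.event_vector(e.etype))
            for c in e.children:
                for i in range(3):
                    total[i] += c.v[i]
            assert tuple(total) == e.parent.v, (e, e.parent.v, tuple(total))
            self._check_postlist(e)

    def _check_postlist(self, e: EventNode) -> None:
        gn = self.gene_tree.nodes[e.parent.u]
        xn = self.sp.nodes[e.parent.x]
        pl = ev.postlist(e.etype, gn, xn, self.sp)
        if e.etype in ev.BIRTH_EVENTS:
            got = {(c.u, c.x) for c in e.children}
            assert any({(g.name, s.name) for g, s in alt} == got for alt in pl)
        else:
            c = e.children[0]
            assert any((g.name, s.name) == (c.u, c.x) for g, s in pl)


# ---------------------------------------------------------------------------
# construction


class _Builder:
    def __init__(self, gene_tree: GeneTree, sp: SubdividedTree,
                 matrix: ParetoMatrix):
        self.G = gene_tree
        self.sp = sp
        self.matrix = matrix
        self.final_sets = {k: frozenset(v) for k, v in matrix.final.items()}
        self.phase1_sets = {k: frozenset(v) for k, v in matrix.phase1.items()}
        self.memo: Dict[MappingKey, Optional[MappingNode]] = {}
        self.event_nodes: List[EventNode] = []

    # -- tag normalization

    def norm_key(self, u: str, x: SpeciesNode, v: Vector, entry: str,
                 no_tl: bool) -> MappingKey:
        if x.kind != "artificial" and entry == NONEMPTY:
            entry = ANY  # no crossing exists there anyway
        if no_tl and not self.sp.co_timed(x):
            no_tl = False
        return MappingKey(u, x.name, v, entry, no_tl)

    def expand(self, u: str, x: SpeciesNode, v: Vector, entry: str,
               no_tl: bool) -> Optional[MappingNode]:
        key = self.norm_key(u, x, v, entry, no_tl)
        if key in self.memo:
            got = self.memo[key]
            if got == "_IN_PROGRESS":  # pragma: no cover - structural guard
                raise AssertionError(f"cyclic expansion at {key}")
            return got
        self.memo[key] = "_IN_PROGRESS"
        node = MappingNode(key)
        events = self._events_for(node, x)
        if not events:
            self.memo[key] = None
            return None
        events.sort(key=_event_sort_key)
        node.events = events
        for e in events:
            e.parent = node
            for c in e.children:
                c.parents.append(e)
        self.event_nodes.extend(events)
        self.memo[key] = node
        return node

    # -- event enumeration

    def _events_for(self, node: MappingNode, x: SpeciesNode) -> List[EventNode]:
        u, v, entry, no_tl = node.key.u, node.key.v, node.key.entry, node.key.no_tl
        gn = self.G.nodes[u]
        out: List[EventNode] = []

        # no-event crossing of an artificial node
        if (x.kind == "artificial"
                and entry in (ANY, ONLYEMPTY, ONLYEMPTY_TL)):
            x1 = x.children[0]
            if v in self.final_sets[u, x1.name]:
                sub_entry = ONLYTL if entry == ONLYEMPTY_TL else ANY
                child = self.expand(u, x1, v, sub_entry, False)
                if child is not None:
                    out.append(EventNode(ev.EMPTY, None, (child,)))
        if entry in (ONLYEMPTY, ONLYEMPTY_TL):
            return out
        only_tl = entry == ONLYTL

        # contemporary event
        if (not only_tl and gn.is_leaf and x.kind == "leaf"
                and x.species == gn.species and v == (0, 0, 0)):
            rec = EventRecord(ev.C, u, (x.name,))
            out.append(EventNode(ev.C, None, (), record=rec))

        # speciation / speciation-loss at a speciation node
        if x.kind == "speciation" and not only_tl:
            x1, x2 = x.children
            for survivor, other in ((x1, x2), (x2, x1)):
                w = _sub(v, ev.event_vector(ev.SL))
                if w is not None and w in self.final_sets[u, survivor.name]:
                    child = self.expand(u, survivor, w, ANY, False)
                    if child is not None:
                        rec = EventRecord(ev.SL, u, (x.name, survivor.s_branch))
                        out.append(EventNode(ev.SL, None, (child,), record=rec))
            if not gn.is_leaf:
                u1, u2 = (c.name for c in gn.children)
                rec = EventRecord(ev.S, u, (x.name,))
                for (ua, xa), (ub, xb) in (((u1, x1), (u2, x2)),
                                           ((u1, x2), (u2, x1))):
                    for c1, c2 in self._splits(v, ua, xa, ub, xb,
                                               [(ANY, ANY)]):
                        out.append(EventNode(ev.S, None, (c1, c2), record=rec))

        # duplication (any node kind)
        if not gn.is_leaf and not only_tl:
            u1, u2 = (c.name for c in gn.children)
            w = _sub(v, ev.event_vector(ev.D))
            if w is not None:
                combos = ([(NONEMPTY, ANY), (ONLYEMPTY, NONEMPTY)]
                          if x.kind == "artificial" else [(ANY, ANY)])
                rec = EventRecord(ev.D, u, (x.s_branch,))
                for c1, c2 in self._splits(w, u1, x, u2, x, combos):
                    out.append(EventNode(ev.D, None, (c1, c2), record=rec))

        # transfer / transfer-loss to a co-timed node
        for z in self.sp.co_timed(x):
            unpinned = x.kind == "artificial" and z.kind == "artificial"
            if not gn.is_leaf and not only_tl:
                u1, u2 = (c.name for c in gn.children)
                w = _sub(v, ev.event_vector(ev.T))
                if w is not None:
                    combos = ([(NONEMPTY, ANY), (ONLYEMPTY, NONEMPTY)]
                              if unpinned else [(ANY, ANY)])
                    rec = EventRecord(ev.T, u, (x.s_branch, z.s_branch))
                    for ua, ub in ((u1, u2), (u2, u1)):
                        for c1, c2 in self._splits(w, ua, x, ub, z, combos):
                            out.append(EventNode(ev.T, None, (c1, c2),
                                                 receiver=z.name, record=rec))
            if not no_tl:
                w = _sub(v, ev.event_vector(ev.TL))
                if w is not None and w in self.phase1_sets[u, z.name]:
                    # pinned TL: free continuation.  Unpinned TL: either the
                    # continuation starts with a real event (which pins or
                    # blocks recursively) or it is a crossing followed by a
                    # TL, blocking the downward shift.
                    tags = ([NONEMPTY, ONLYEMPTY_TL] if unpinned else [ANY])
                    rec = EventRecord(ev.TL, u, (x.s_branch, z.s_branch))
                    for tag in tags:
                        child = self.expand(u, z, w, tag, True)
                        if child is not None:
                            out.append(EventNode(ev.TL, None, (child,),
                                                 receiver=z.name, record=rec))
        return out

    def _splits(self, target: Vector, ua: str, xa: SpeciesNode, ub: str,
                xb: SpeciesNode, combos) -> Iterator[Tuple[MappingNode, MappingNode]]:
        """Decompositions target = w1 + w2 with w1, w2 in the children lists,
        expanded under each admissible entry-tag combination."""
        lb = self.final_sets[ub, xb.name]
        for w1 in self.matrix.final[ua, xa.name]:
            w2 = _sub(target, w1)
            if w2 is None or w2 not in lb:
                continue
            for t1, t2 in combos:
                c1 = self.expand(ua, xa, w1, t1, False)
                if c1 is None:
                    continue
                c2 = self.expand(ub, xb, w2, t2, False)
                if c2 is None:
                    continue
                yield c1, c2


def _sub(v: Vector, w: Vector) -> Optional[Vector]:
    r = (v[0] - w[0], v[1] - w[1], v[2] - w[2])
    return r if min(r) >= 0 else None


def _event_sort_key(e: EventNode):
    return (_EVENT_ORDER[e.etype], e.receiver or "",
            tuple(c.key for c in e.children))


def build_graph(gene_tree: GeneTree, sp: SubdividedTree, matrix: ParetoMatrix,
                retained_roots: Sequence[Vector]) -> ReconciliationGraph:
    """Backtrack the DP matrix into the minimal reconciliation graph.

    Roots are created for every S' node x and vector v in C(root, x) that is
    also in ``retained_roots``; expansion recursively matches every event
    decomposition against the stored Pareto lists (TL children against the
    TL-free phase lists) and prunes non-canonical placements via entry tags.
    """
    retained = set(retained_roots)
    if not retained:
        raise ValueError("no retained root vectors")
    b = _Builder(gene_tree, sp, matrix)
    rname = gene_tree.root.name
    roots = []
    for x in sorted(sp.postorder(), key=lambda n: n.name):
        for v in matrix.final[rname, x.name]:
            if v in retained:
                node = b.expand(rname, x, v, NONEMPTY, False)
                if node is not None:
                    roots.append(node)
    if not roots:
        raise AssertionError("no viable roots: canonical representative lost")
    # drop nodes only reachable from abandoned expansion paths
    live_m, live_e = set(), set()
    stack = list(roots)
    while stack:
        m = stack.pop()
        if id(m) in live_m:
            continue
        live_m.add(id(m))
        for e in m.events:
            live_e.add(id(e))
            stack.extend(e.children)
    mapping_nodes = {}
    for k, n in b.memo.items():
        if n is not None and id(n) in live_m:
            n.parents = [p for p in n.parents if id(p) in live_e]
            mapping_nodes[k] = n
    event_nodes = [e for e in b.event_nodes if id(e) in live_e]
    return ReconciliationGraph(gene_tree, sp, roots, mapping_nodes,
                               event_nodes)


# ---------------------------------------------------------------------------
# enumeration and counting


def enumerate_full_subtrees(graph: ReconciliationGraph,
                            limit: Optional[int] = None) -> List[Reconciliation]:
    """Reconciliations depicted by the graph's full subtrees.

    A full subtree picks one root, one event child per mapping node, and keeps
    every child of each chosen event node.  Enumeration order is deterministic
    (roots and event children in stored order).
    """
    if limit is not None and limit <= 0:
        raise ValueError("limit must be positive")

    def choices(m: MappingNode):
        for e in m.events:
            for subs in product(*(choices(c) for c in e.children)):
                yield (m, e, subs)

    def all_choices():
        for root in graph.roots:
            yield from choices(root)

    out = []
    gen = all_choices() if limit is None else islice(all_choices(), limit)
    for tree in gen:
        mapping: Dict[str, List[str]] = {}
        stack = [tree]
        while stack:
            m, e, subs = stack.pop()
            mapping.setdefault(m.u, []).append(m.x)
            if e.etype in (ev.EMPTY, ev.SL, ev.TL):
                stack.append(subs[0])
            elif e.etype in ev.BIRTH_EVENTS:
                # children first-to-last so sequences extend in order
                stack.extend(reversed(subs))
        out.append(Reconciliation(mapping, graph.gene_tree, graph.sp))
    return out


def count_reconciliations(graph: ReconciliationGraph) -> int:
    """Number of reconciliations depicted by the graph (exact, big ints)."""
    from .supports import compute_scores

    scores = compute_scores(graph)
    return sum(scores[id(r)] for r in graph.roots)
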