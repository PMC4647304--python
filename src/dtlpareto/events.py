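"""The DTL event model: event types, event count vectors, the postlist
transition function, explicit reconciliations and their species-level event
records.

A reconciliation maps every gene-tree node u onto an ordered sequence of nodes
of the subdivided species tree S'.  Each position of a sequence carries exactly
one event: the last position a birth event (speciation S, duplication D,
transfer T) for internal gene nodes or a contemporary event C for gene leaves;
every other position a slice-crossing event (speciation-loss SL, transfer-loss
TL, or the no-event crossing of an artificial node).  Losses never occur alone
(a lone duplication-loss would make the solution space infinite) and two TL
events may not be consecutive for the same reason.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Tuple

from .trees import GeneNode, GeneTree, SpeciesNode, SubdividedTree

__all__ = [
    "S", "D", "T", "C", "SL", "TL", "EMPTY",
    "BIRTH_EVENTS", "EVENT_TYPES",
    "event_vector", "dominates", "cost_of", "postlist",
    "EventRecord", "atomic_records",
    "Reconciliation", "ReconciliationError", "validate_reconciliation",
    "is_canonical",
]

# Event type codes.  Kept as short strings: they appear verbatim in text
# output and TSV files.
S = "S"
D = "D"
T = "T"
C = "C"
SL = "SL"
TL = "TL"
EMPTY = "O"  # the no-event slice crossing (often written as a slashed zero)

BIRTH_EVENTS = (S, D, T)
EVENT_TYPES = (S, D, T, C, SL, TL, EMPTY)

_EVENT_VECTORS = {
    S: (0, 0, 0),
    C: (0, 0, 0),
    EMPTY: (0, 0, 0),
    D: (1, 0, 0),
    T: (0, 1, 0),
    SL: (0, 0, 1),
    TL: (0, 1, 1),
}

Vector = Tuple[int, int, int]


def event_vector(e: str) -> Vector:
    """Event count vector (d, t, l) of a single event."""
    return _EVENT_VECTORS[e]


def dominates(v: Vector, w: Vector) -> str:
    """Componentwise comparison of two count vectors.

    Returns one of ``"strictly_less"``, ``"equal"``, ``"strictly_greater"``,
    ``"incomparable"`` (the partial order of the Pareto front).
    """
    le = all(a <= b for a, b in zip(v, w))
    ge = all(a >= b for a, b in zip(v, w))
    if le and ge:
        return "equal"
    if le:
        return "strictly_less"
    if ge:
        return "strictly_greater"
    return "incomparable"


def cost_of(v: Vector, costs: Sequence[float]) -> float:
    """Dot product of a count vector with a cost vector (delta, tau, lambda)."""
    d, t, l = costs
    if d <= 0 or t <= 0 or l <= 0:
        raise ValueError("event costs must be strictly positive")
    return v[0] * d + v[1] * t + v[2] * l


# ---------------------------------------------------------------------------
# postlist


def postlist(e: str, u: GeneNode, x: SpeciesNode, sp: SubdividedTree):
    """Possible next mappings after event ``e`` at gene node ``u``, S' node ``x``.

    For birth events (S, D, T) the result is a list of *sets* of
    (gene node, S' node) pairs (one set per alternative child assignment);
    for SL, TL and the no-event crossing it is a list of single pairs.
    An empty list signals that the event cannot occur at (u, x).
    """
    internal = not u.is_leaf
    if e == S:
        if internal and x.kind == "speciation":
            x1, x2 = x.children
            u1, u2 = u.children
            return [{(u1, x1), (u2, x2)}, {(u1, x2), (u2, x1)}]
        return []
    if e == D:
        if internal:
            u1, u2 = u.children
            return [{(u1, x), (u2, x)}]
        return []
    if e == T:
        if internal:
            u1, u2 = u.children
            out = []
            for z in sp.co_timed(x):
                out.append({(u1, x), (u2, z)})
                out.append({(u2, x), (u1, z)})
            return out
        return []
    if e == EMPTY:
        if x.kind == "artificial":
            return [(u, x.children[0])]
        return []
    if e == SL:
        if x.kind == "speciation":
            return [(u, x.children[0]), (u, x.children[1])]
        return []
    if e == TL:
        return [(u, z) for z in sp.co_timed(x)]
    raise ValueError(f"unknown event type {e!r}")


# ---------------------------------------------------------------------------
# species-level event records


class EventRecord(NamedTuple):
    """A species-located event identity.

    Locations refer to the *species tree* (via the branch back-map of S'), so
    two placements of the same event in different slices of one branch compare
    equal.  ``loc`` is, by type:

    * D and the no-event crossing: (branch,)
    * S: (speciation node,)
    * SL: (speciation node, surviving child branch)
    * T / TL: (donor branch, receiver branch)
    * C: (species leaf,)

    ``gene`` is the gene-tree node carrying the event; it is part of the
    identity for support computation and dropped when comparing predictions
    against simulated truths (a simulated lineage has no identity in an
    inferred tree).
    """

    etype: str
    gene: Optional[str]
    loc: Tuple[str, ...]

    def drop_gene(self) -> "EventRecord":
        return EventRecord(self.etype, None, self.loc)


def atomic_records(rec: EventRecord, species_tree) -> List[EventRecord]:
    """Decompose a composite event into atomic D/T/L records (gene dropped).

    D -> {D}; T -> {T}; SL -> {L on the lost child branch};
    TL -> {T, L on the donor branch}; S, C and the no-event crossing -> {}.
    """
    if rec.etype == D:
        return [EventRecord(D, None, rec.loc)]
    if rec.etype == T:
        return [EventRecord(T, None, rec.loc)]
    if rec.etype == SL:
        spec, survivor = rec.loc
        lost = [b for b in species_tree.child_branches(spec) if b != survivor]
        return [EventRecord("L", None, (lost[0],))]
    if rec.etype == TL:
        donor, receiver = rec.loc
        return [EventRecord(T, None, rec.loc), EventRecord("L", None, (donor,))]
    return []


# ---------------------------------------------------------------------------
# reconciliations


class ReconciliationError(ValueError):
    """Raised when a mapping violates the reconciliation model; carries the
    offending (gene node, position index, S' node) when applicable."""

    def __init__(self, message, where=None):
        super().__init__(message)
        self.where = where


class _Position(NamedTuple):
    x: str                    # S' node name
    event: str                # event code at this position
    aux: Optional[str]        # receiver S' node for T/TL, else None


class Reconciliation:
    """An explicit reconciliation: per gene node, an ordered S'-node sequence.

    Events are derived from the sequences (the model guarantees each position
    matches exactly one clause) and checked on construction.
    """

    def __init__(self, mapping: Dict[str, Sequence[str]], gene_tree: GeneTree,
                 sp: SubdividedTree):
        self.gene_tree = gene_tree
        self.sp = sp
        self.mapping = {u: tuple(xs) for u, xs in mapping.items()}
        self.positions: Dict[str, Tuple[_Position, ...]] = {}
        self._annotate()

    # -- derivation / validation

    def _annotate(self) -> None:
        G, sp = self.gene_tree, self.sp
        for u in G.postorder():
            if u.name not in self.mapping or not self.mapping[u.name]:
                raise ReconciliationError(f"gene node {u.name!r} unmapped")
        for u in G.postorder():
            seq = self.mapping[u.name]
            if len(set(seq)) != len(seq):
                raise ReconciliationError(
                    f"repeated S' node in the sequence of {u.name!r}", (u.name,))
            annotated = []
            for i, xname in enumerate(seq):
                x = sp.nodes.get(xname)
                if x is None:
                    raise ReconciliationError(
                        f"unknown S' node {xname!r}", (u.name, i, xname))
                last = i == len(seq) - 1
                if last:
                    annotated.append(self._final_event(u, x, i))
                else:
                    annotated.append(self._crossing_event(u, x, seq[i + 1], i))
            for a, b in zip(annotated, annotated[1:]):
                if a.event == TL and b.event == TL:
                    raise ReconciliationError(
                        f"consecutive TL events in the sequence of {u.name!r}",
                        (u.name,))
            self.positions[u.name] = tuple(annotated)

    def _final_event(self, u: GeneNode, x: SpeciesNode, i: int) -> _Position:
        where = (u.name, i, x.name)
        if u.is_leaf:
            if x.kind == "leaf" and x.species == u.species:
                return _Position(x.name, C, None)
            raise ReconciliationError(
                f"gene leaf {u.name!r} (species {u.species}) ends at "
                f"{x.name!r}", where)
        u1, u2 = u.children
        c1 = self.mapping.get(u1.name, ("?",))[0]
        c2 = self.mapping.get(u2.name, ("?",))[0]
        if x.kind == "speciation":
            kids = {c.name for c in x.children}
            if {c1, c2} == kids and c1 != c2:
                return _Position(x.name, S, None)
        if c1 == x.name and c2 == x.name:
            return _Position(x.name, D, None)
        co = {z.name for z in self.sp.co_timed(x)}
        if c1 == x.name and c2 in co:
            return _Position(x.name, T, c2)
        if c2 == x.name and c1 in co:
            return _Position(x.name, T, c1)
        raise ReconciliationError(
            f"no birth event matches children placements ({c1!r}, {c2!r}) "
            f"of {u.name!r} at {x.name!r}", where)

    def _crossing_event(self, u: GeneNode, x: SpeciesNode, nxt: str,
                        i: int) -> _Position:
        where = (u.name, i, x.name)
        if x.kind == "artificial" and nxt == x.children[0].name:
            return _Position(x.name, EMPTY, None)
        if x.kind == "speciation" and nxt in {c.name for c in x.children}:
            return _Position(x.name, SL, nxt)
        if nxt in {z.name for z in self.sp.co_timed(x)}:
            return _Position(x.name, TL, nxt)
        raise ReconciliationError(
            f"cannot advance from {x.name!r} to {nxt!r} in the sequence of "
            f"{u.name!r}", where)

    # -- derived quantities

    def vector(self) -> Vector:
        d = t = l = 0
        for poss in self.positions.values():
            for p in poss:
                vd, vt, vl = _EVENT_VECTORS[p.event]
                d, t, l = d + vd, t + vt, l + vl
        return (d, t, l)

    def records(self, include_neutral: bool = False) -> List[EventRecord]:
        """Species-level event records; neutral = C and no-event crossings."""
        out = []
        sp = self.sp
        for uname, poss in self.positions.items():
            for p in poss:
                x = sp.nodes[p.x]
                e = p.event
                if e == EMPTY:
                    if include_neutral:
                        out.append(EventRecord(EMPTY, uname, (x.s_branch,)))
                    continue
                if e == C:
                    if include_neutral:
                        out.append(EventRecord(C, uname, (x.name,)))
                    continue
                if e == D:
                    out.append(EventRecord(D, uname, (x.s_branch,)))
                elif e == S:
                    out.append(EventRecord(S, uname, (x.name,)))
                elif e == SL:
                    survivor = sp.nodes[p.aux]
                    out.append(EventRecord(SL, uname, (x.name, survivor.s_branch)))
                elif e in (T, TL):
                    z = sp.nodes[p.aux]
                    out.append(EventRecord(e, uname, (x.s_branch, z.s_branch)))
        return out

    def atomic_multiset(self):
        """Counter of atomic D/T/L records (gene identity dropped)."""
        from collections import Counter
        st = self.sp.species_tree
        out: "Counter[EventRecord]" = Counter()
        for rec in self.records():
            for a in atomic_records(rec, st):
                out[a] += 1
        return out

    def to_text(self) -> str:
        """One line per gene node: ``u: x1[e1], x2[e2], ...``."""
        lines = []
        for u in self.gene_tree.postorder():
            parts = []
            for p in self.positions[u.name]:
                tag = f"{p.event}->{p.aux}" if p.aux and p.event in (T, TL) else p.event
                parts.append(f"{p.x}[{tag}]")
            lines.append(f"{u.name}: " + ", ".join(parts))
        return "\n".join(lines)

    # equality on the S'-level mapping (used by oracle tests)
    def key(self) -> tuple:
        return tuple(sorted(self.mapping.items()))

    def __eq__(self, other):
        return isinstance(other, Reconciliation) and self.key() == other.key()

    def __hash__(self):
        return hash(self.key())


def validate_reconciliation(mapping: Dict[str, Sequence[str]],
                            gene_tree: GeneTree,
                            sp: SubdividedTree) -> List[EventRecord]:
    """Check a mapping against the model; return its event records.

    Raises :class:`ReconciliationError` locating the first violating
    (gene node, position, S' node) otherwise.
    """
    return Reconciliation(mapping, gene_tree, sp).records()


# ---------------------------------------------------------------------------
# canonical form


def is_canonical(rec: Reconciliation) -> bool:
    """True if every event sits as low as possible within its species branch.

    Placements of D, T and TL events can shift between the artificial nodes of
    a branch without changing the species-level events.  A reconciliation is
    the canonical representative of its equivalence class iff

    * the root's sequence does not start with a no-event crossing (leading
      crossings have no species-level trace and a lower starting point exists),
      and
    * no event whose S' endpoints are all artificial has a forward same-slice
      closure free of *pinned* and *blocked* events.  The closure of an event
      collects the later events of the lineages it produces for as long as
      they stay in the same time slice; an event is pinned when one of its
      endpoints is not artificial (speciation node or leaf), and a TL event is
      blocked when its continuation is a no-event crossing followed
      immediately by another TL — shifting it down would chain two TLs, which
      the model forbids.  An unpinned, unblocked closure exiting only through
      no-event crossings can be shifted one slice down wholesale, so the
      reconciliation is not the lowest representative.
    """
    sp = rec.sp
    root_name = rec.gene_tree.root.name
    if rec.positions[root_name][0].event == EMPTY:
        return False

    def pinned(p: _Position) -> bool:
        x = sp.nodes[p.x]
        if x.kind != "artificial":
            return True
        if p.event in (T, TL) and sp.nodes[p.aux].kind != "artificial":
            return True
        return False

    def successors(uname: str, i: int):
        """Lineage positions produced by event (uname, i) that stay in-slice."""
        p = rec.positions[uname][i]
        x = sp.nodes[p.x]
        t = x.time
        out = []
        if p.event == D or p.event == T:
            u = rec.gene_tree.nodes[uname]
            for child in u.children:
                first = sp.nodes[rec.mapping[child.name][0]]
                if first.time == t:
                    out.append((child.name, 0))
        elif p.event == TL:
            out.append((uname, i + 1))
        return out

    def blocked(uname: str, i: int) -> bool:
        poss = rec.positions[uname]
        return (poss[i].event == TL and poss[i + 1].event == EMPTY
                and poss[i + 2].event == TL)

    def closure_pinned(uname: str, i: int, seen: set) -> bool:
        if (uname, i) in seen:
            return False
        seen.add((uname, i))
        p = rec.positions[uname][i]
        if p.event == EMPTY:
            return False  # exits the slice: contributes no pin
        if pinned(p) or blocked(uname, i):
            return True
        return any(closure_pinned(v, j, seen) for v, j in successors(uname, i))

    for uname, poss in rec.positions.items():
        for i, p in enumerate(poss):
            if p.event in (D, T, TL) and not pinned(p):
                if not closure_pinned(uname, i, set()):
                    return False
    return True
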