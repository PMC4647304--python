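"""Synthetic data: dated species trees, DTL gene-family histories, the
exhaustive reconciliation oracle, and the event-prediction error metric.

The history generator is a discrete-time analogue of a birth-and-death process
along a dated species phylogeny: a gene lineage traverses the tree one time
slice at a time and may, per slice segment, duplicate, transfer to a uniformly
chosen co-timed other branch, or die.  Rates are per gene per million years;
a slice corresponds to ``slice_span_my`` million years (time ranks are ordinal,
so the span sets the effective depth of the tree).  Extinct subtrees are
pruned from the returned gene tree; their internal events are dropped and a
single loss is recorded at each pruning point, mirroring what is knowable from
surviving lineages plus the loss that explains each disappearance.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import events as ev
from .events import EventRecord, Reconciliation
from .trees import (DatedSpeciesTree, GeneNode, GeneTree, SpeciesNode,
                    SubdividedTree, subdivide)

__all__ = ["SimRates", "TrueHistory", "AllLineagesExtinct",
           "random_dated_species_tree", "simulate_history",
           "perturb_gene_tree", "enumerate_reconciliations_bruteforce",
           "BruteForceLimit", "evaluate_events"]


class AllLineagesExtinct(RuntimeError):
    """The simulated family died out completely; retry with another seed."""


@dataclass(frozen=True)
class SimRates:
    """Rates of the gene birth-and-death process.

    loss_rate: losses per gene per million years.
    birth_loss_ratio: (duplication + transfer rate) / loss rate.
    dup_proportion: share of the birth rate due to duplications.
    slice_span_my: million years represented by one time-rank step; time
        ranks are ordinal, so this calibrates how much evolution one slice
        holds.

    Defaults follow the simulation design this generator emulates: loss rate
    uniform in [0.001, 0.0018], birth/loss ratio in [0.5, 1.1], duplication
    proportion in [0.7, 1].  ``draw`` samples a rate set from those intervals.
    """

    loss_rate: float = 0.0014
    birth_loss_ratio: float = 0.8
    dup_proportion: float = 0.85
    slice_span_my: float = 100.0

    LOSS_INTERVAL = (0.001, 0.0018)
    BIRTH_LOSS_INTERVAL = (0.5, 1.1)
    DUP_PROPORTION_INTERVAL = (0.7, 1.0)

    def __post_init__(self):
        if self.loss_rate < 0 or self.slice_span_my <= 0:
            raise ValueError("invalid rates")
        if not 0 <= self.dup_proportion <= 1 or self.birth_loss_ratio < 0:
            raise ValueError("invalid rates")

    @property
    def birth_rate(self) -> float:
        return self.birth_loss_ratio * self.loss_rate

    @property
    def dup_rate(self) -> float:
        return self.dup_proportion * self.birth_rate

    @property
    def transfer_rate(self) -> float:
        return (1 - self.dup_proportion) * self.birth_rate

    @classmethod
    def draw(cls, rng: np.random.Generator, slice_span_my: float = 100.0
             ) -> "SimRates":
        return cls(
            loss_rate=rng.uniform(*cls.LOSS_INTERVAL),
            birth_loss_ratio=rng.uniform(*cls.BIRTH_LOSS_INTERVAL),
            dup_proportion=rng.uniform(*cls.DUP_PROPORTION_INTERVAL),
            slice_span_my=slice_span_my,
        )


@dataclass
class TrueHistory:
    """A simulated gene family: surviving gene tree plus true event records.

    ``records`` lists composite species-located events (S, D, T, L) of the
    pruned history, gene-anonymous; ``dtl_multiset()`` gives the atomic D/T/L
    multiset used for accuracy evaluation.
    """

    gene_tree: GeneTree
    records: List[EventRecord]

    def dtl_multiset(self) -> Counter:
        return Counter(r for r in self.records if r.etype in (ev.D, ev.T, "L"))

    def counts(self) -> Dict[str, int]:
        c = Counter(r.etype for r in self.records)
        return {k: c.get(k, 0) for k in (ev.S, ev.D, ev.T, "L")}


# ---------------------------------------------------------------------------
# species tree generation


def _species_names(n: int) -> List[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"S{i + 1}" for i in range(n)]


def random_dated_species_tree(n_leaves: int,
                              rng_or_seed) -> DatedSpeciesTree:
    """Random binary topology with ranks assigned in coalescence order.

    Lineages are merged two at a time, uniformly at random; the k-th merge
    gets time rank k, which automatically yields a strict total order
    consistent with the ancestry relation.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 species")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    lineages = [SpeciesNode(name) for name in _species_names(n_leaves)]
    for l in lineages:
        l.species = l.name
    rank = 0
    while len(lineages) > 1:
        rank += 1
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = SpeciesNode(f"t{rank}", time=rank)
        node.add_child(lineages[i])
        node.add_child(lineages[j])
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(node)
    return DatedSpeciesTree(lineages[0])


# ---------------------------------------------------------------------------
# gene history simulation


def simulate_history(species_tree: DatedSpeciesTree, rates: SimRates,
                     rng_or_seed) -> TrueHistory:
    """Simulate one gene family along the species tree.

    One gene copy enters at the species root; per slice segment it undergoes
    at most one event (competing risks, probabilities 1 - exp(-rate * span)
    partitioned proportionally to the rates).  Transfers pick the receiving
    co-timed branch uniformly.  Raises :class:`AllLineagesExtinct` when no
    copy survives.
    """
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    sp = subdivide(species_tree)
    span = rates.slice_span_my
    r_d, r_t, r_l = rates.dup_rate, rates.transfer_rate, rates.loss_rate
    total = r_d + r_t + r_l
    p_any = 1.0 - float(np.exp(-total * span)) if total > 0 else 0.0
    leaf_counter = [0]

    def co_timed_edges(x: SpeciesNode) -> List[SpeciesNode]:
        # segments at x's slice are identified by their bottom node
        return [z for z in sp.slices[x.time] if z is not x]

    def at_node(x: SpeciesNode):
        """Lineage arriving at S' node x; returns (gene node | None, records)."""
        if x.kind == "leaf":
            leaf_counter[0] += 1
            leaf = GeneNode(f"g{leaf_counter[0]}_{x.species}",
                            species=x.species)
            return leaf, []
        if x.kind == "artificial":
            return on_edge(x.children[0])
        left, lrec = on_edge(x.children[0])
        right, rrec = on_edge(x.children[1])
        srec = EventRecord(ev.S, None, (x.name,))
        if left is not None and right is not None:
            return _join(left, right), [srec] + lrec + rrec
        if left is not None:
            return left, lrec + [srec, _loss(x.children[1])]
        if right is not None:
            return right, rrec + [srec, _loss(x.children[0])]
        return None, []

    def on_edge(x: SpeciesNode):
        """Lineage traversing the slice segment that ends at S' node x."""
        if p_any > 0 and rng.random() < p_any:
            kind = rng.choice(3, p=[r_d / total, r_t / total, r_l / total])
            if kind == 2:  # loss: this segment is its own pruning point
                return None, []
            if kind == 0:  # duplication
                a, arec = on_rest(x)
                b, brec = on_rest(x)
                drec = EventRecord(ev.D, None, (x.s_branch,))
                return _merge_birth(a, arec, b, brec, drec,
                                    (x.s_branch,), (x.s_branch,))
            # transfer
            others = co_timed_edges(x)
            if not others:
                return on_rest(x)  # nowhere to go; the attempt fizzles
            z = others[int(rng.integers(len(others)))]
            a, arec = on_rest(x)      # donor copy
            b, brec = at_node(z)      # transferred copy continues from z
            trec = EventRecord(ev.T, None, (x.s_branch, z.s_branch))
            return _merge_birth(a, arec, b, brec, trec,
                                (x.s_branch,), (z.s_branch,))
        return at_node(x)

    def on_rest(x: SpeciesNode):
        """Continue within the same segment after a birth event (at most one
        event per copy per slice: the rest of the segment is event-free)."""
        return at_node(x)

    def _loss(x: SpeciesNode) -> EventRecord:
        return EventRecord("L", None, (x.s_branch,))

    def _merge_birth(a, arec, b, brec, birth, loc_a, loc_b):
        if a is not None and b is not None:
            return _join(a, b), [birth] + arec + brec
        if a is not None:
            return a, arec + [birth, EventRecord("L", None, loc_b)]
        if b is not None:
            return b, brec + [birth, EventRecord("L", None, loc_a)]
        return None, []

    root, records = at_node(sp.root)
    if root is None:
        raise AllLineagesExtinct("the simulated family left no descendants")
    _name_internals(root)
    return TrueHistory(GeneTree(root), records)


def _join(a: GeneNode, b: GeneNode) -> GeneNode:
    node = GeneNode("tmp")
    node.add_child(a)
    node.add_child(b)
    return node


def _name_internals(root: GeneNode) -> None:
    k = 0
    for n in root.postorder():
        if not n.is_leaf:
            k += 1
            n.name = f"n{k}"


def perturb_gene_tree(gene_tree: GeneTree, n_swaps: int,
                      rng_or_seed) -> GeneTree:
    """Inject topological error by swapping random leaf label pairs."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    from .trees import parse_gene_tree

    tree = parse_gene_tree(gene_tree.newick(), sep="_")
    leaves = tree.leaves
    for _ in range(n_swaps):
        if len(leaves) < 2:
            break
        i, j = rng.choice(len(leaves), size=2, replace=False)
        leaves[i].name, leaves[j].name = leaves[j].name, leaves[i].name
        leaves[i].species, leaves[j].species = (leaves[j].species,
                                                leaves[i].species)
    return parse_gene_tree(tree.newick(), sep="_")


# ---------------------------------------------------------------------------
# brute-force oracle


class BruteForceLimit(RuntimeError):
    """Raised when exhaustive enumeration exceeds the instance-size guard."""


def enumerate_reconciliations_bruteforce(
        gene_tree: GeneTree, sp: SubdividedTree,
        canonical_only: bool = False,
        max_count: int = 2_000_000) -> List[Reconciliation]:
    """Exhaustively enumerate the reconciliations between G and S'.

    Direct recursion over the model's clauses (with the no-consecutive-TL
    rule), independent of the dynamic program — the test oracle for the DP,
    the reconciliation graph and the support recursions.  Guarded to small
    instances (at most 7 gene and 6 species leaves).  With ``canonical_only``
    the list is restricted to canonical representatives.
    """
    if len(gene_tree.leaves) > 7 or len(sp.species_tree.leaves) > 6:
        raise BruteForceLimit("instance too large for exhaustive enumeration")

    memo: Dict[Tuple[str, str, bool], list] = {}

    def rec(u: GeneNode, x: SpeciesNode, no_tl: bool) -> list:
        """Partial reconciliations of G_u with first mapping x, as tuples of
        (gene node name, sequence) pairs."""
        key = (u.name, x.name, no_tl)
        if key in memo:
            return memo[key]
        out = []
        # contemporary
        if u.is_leaf and x.kind == "leaf" and x.species == u.species:
            out.append(((u.name, (x.name,)),))
        # no-event crossing
        if x.kind == "artificial":
            for part in rec(u, x.children[0], False):
                out.append(_prepend(part, u.name, x.name))
        if x.kind == "speciation":
            x1, x2 = x.children
            for nxt in (x1, x2):  # speciation-loss
                for part in rec(u, nxt, False):
                    out.append(_prepend(part, u.name, x.name))
            if not u.is_leaf:  # speciation
                u1, u2 = u.children
                for a, b in ((x1, x2), (x2, x1)):
                    for p1 in rec(u1, a, False):
                        for p2 in rec(u2, b, False):
                            out.append(((u.name, (x.name,)),) + p1 + p2)
        if not u.is_leaf:
            u1, u2 = u.children
            for p1 in rec(u1, x, False):  # duplication
                for p2 in rec(u2, x, False):
                    out.append(((u.name, (x.name,)),) + p1 + p2)
            for z in sp.co_timed(x):  # transfer
                for ua, ub in ((u1, u2), (u2, u1)):
                    for p1 in rec(ua, x, False):
                        for p2 in rec(ub, z, False):
                            out.append(((u.name, (x.name,)),) + p1 + p2)
        if not no_tl:  # transfer-loss
            for z in sp.co_timed(x):
                for part in rec(u, z, True):
                    out.append(_prepend(part, u.name, x.name))
        if len(out) > max_count:
            raise BruteForceLimit("enumeration exceeded the size guard")
        memo[key] = out
        return out

    root = gene_tree.root
    results: List[Reconciliation] = []
    for x in sp.postorder():
        for part in rec(root, x, False):
            mapping: Dict[str, Tuple[str, ...]] = dict(part)
            results.append(Reconciliation(mapping, gene_tree, sp))
            if len(results) > max_count:
                raise BruteForceLimit("enumeration exceeded the size guard")
    if canonical_only:
        results = [r for r in results if ev.is_canonical(r)]
    return results


def _prepend(part: tuple, uname: str, xname: str) -> tuple:
    """Prefix x to the sequence of u inside a partial solution tuple."""
    (first_u, seq), rest = part[0], part[1:]
    assert first_u == uname
    return ((uname, (xname,) + seq),) + rest


# ---------------------------------------------------------------------------
# evaluation


def evaluate_events(predicted: Counter, truth: Counter
                    ) -> Tuple[int, int, int]:
    """Multiset symmetric distance between predicted and true D/T/L events.

    Returns (FP, FN, FP + FN): events predicted but not simulated, simulated
    but not predicted, and their sum.
    """
    fp = sum((Counter(predicted) - Counter(truth)).values())
    fn = sum((Counter(truth) - Counter(predicted)).values())
    return fp, fn, fp + fn
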