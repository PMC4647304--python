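from collections import Counter
from fractions import Fraction

import pytest

import dtlpareto as dl
from dtlpareto import recgraph as rg
from dtlpareto import supports as sup
from dtlpareto.events import EventRecord
from dtlpareto.recgraph import (EventNode, MappingKey, MappingNode,
                                ReconciliationGraph)

from helpers import oracle_instances, record_distance


def _mapping(name, v=(0, 0, 0)):
    return MappingNode(MappingKey(name, "x", v, "any", False))


def _attach(parent: MappingNode, etype: str, *children: MappingNode,
            record=None) -> EventNode:
    e = EventNode(etype, parent, tuple(children), record=record)
    parent.events.append(e)
    for c in children:
        c.parents.append(e)
    return e


def _graph(roots, mappings, events):
    return ReconciliationGraph(None, None, roots,
                               {m.key: m for m in mappings}, events)


def _leafy(name):
    """Mapping node with a single contemporary child (score 1)."""
    m = _mapping(name)
    e = _attach(m, "C")
    return m, e


class TestCountingFixtures:
    def test_leaf_scores_one(self):
        m, e = _leafy("u")
        g = _graph([m], [m], [e])
        scores = sup.compute_scores(g)
        assert scores[id(m)] == 1 and scores[id(e)] == 1

    def test_sum_and_product_rules(self):
        # two independent binary choice points under one root -> 4
        root = _mapping("r")
        kids = []
        events = []
        for name in ("u1", "u2"):
            m = _mapping(name)
            for k in range(2):
                leaf, ce = _leafy(f"{name}leaf{k}")
                events.append(_attach(m, "SL", leaf))
                events.append(ce)
                kids.append(leaf)
            kids.append(m)
        m1, m2 = kids[2], kids[5]
        events.append(_attach(root, "S", m1, m2))
        g = _graph([root], [root] + kids, events)
        scores = sup.compute_scores(g)
        assert scores[id(m1)] == scores[id(m2)] == 2
        assert scores[id(root)] == 4
        assert rg.count_reconciliations(g) == 4

    def test_recnum_sums_over_parents(self):
        # a mapping node shared by event parents with recNum 2 and 3 gets 5
        shared, shared_c = _leafy("shared")
        a = _mapping("a")
        ea = [_attach(a, "SL", _leafy(f"al{k}")[0]) for k in range(2)]
        b = _mapping("b")
        eb = [_attach(b, "SL", _leafy(f"bl{k}")[0]) for k in range(3)]
        r1, r2 = _mapping("r1"), _mapping("r2")
        p1 = _attach(r1, "S", shared, a)
        p2 = _attach(r2, "S", shared, b)
        mappings = [r1, r2, shared, a, b] + [e.children[0] for e in ea + eb]
        events = [p1, p2, shared_c] + ea + eb
        events += [m.events[0] for e in ea + eb for m in e.children]
        g = _graph([r1, r2], mappings, events)
        scores = sup.compute_scores(g)
        assert scores[id(p1)] == 2 and scores[id(p2)] == 3
        recnum = sup.compute_recnum(g, scores)
        assert recnum[id(p1)] == 2 and recnum[id(p2)] == 3
        assert recnum[id(shared)] == 5
        # conservation at every mapping node
        for m in mappings:
            assert sum(recnum[id(e)] for e in m.events) == recnum[id(m)]

    def test_recnum_is_one_everywhere_on_a_tree(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        m = dl.compute_pareto_matrix(G, cherry_sp)
        graph = rg.build_graph(G, cherry_sp, m, m.root_front)
        scores = sup.compute_scores(graph)
        recnum = sup.compute_recnum(graph, scores)
        assert set(recnum.values()) == {1}


class TestSupportsAgainstOracle:
    def _setup(self, seed):
        for _, _, sp, G, recs in oracle_instances(1, start_seed=seed):
            m = dl.compute_pareto_matrix(G, sp)
            graph = rg.build_graph(G, sp, m, m.root_front)
            canon = [r for r in recs if dl.is_canonical(r)
                     and r.vector() in set(m.root_front)]
            return graph, canon

    @pytest.mark.parametrize("seed", [2, 7, 25, 31])
    def test_frequencies_match_enumeration(self, seed):
        graph, canon = self._setup(seed)
        scores = sup.compute_scores(graph)
        n = rg.count_reconciliations(graph)
        assert n == len(canon)
        recnum = sup.compute_recnum(graph, scores)
        table = sup.event_supports(graph, recnum, n)
        want = Counter()
        for r in canon:
            for rec in set(r.records()):
                want[rec] += 1
        assert set(want) == set(table.composite)
        for key, f in table.composite.items():
            assert f == Fraction(want[key], n)
            assert 0 < f <= 1

    @pytest.mark.parametrize("seed", [2, 7, 25, 31])
    def test_median_minimizes_total_distance(self, seed):
        graph, canon = self._setup(seed)
        scores = sup.compute_scores(graph)
        n = rg.count_reconciliations(graph)
        recnum = sup.compute_recnum(graph, scores)
        table = sup.event_supports(graph, recnum, n)
        med = sup.median_reconciliation(graph, table)
        if n > 400:
            pytest.skip("distance matrix too large for a unit test")
        totals = {r.key(): sum(record_distance(r, o) for o in canon)
                  for r in canon}
        assert totals[med.key()] == min(totals.values())

    def test_single_reconciliation_supports_all_one(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        m = dl.compute_pareto_matrix(G, cherry_sp)
        graph = rg.build_graph(G, cherry_sp, m, m.root_front)
        scores = sup.compute_scores(graph)
        recnum = sup.compute_recnum(graph, scores)
        table = sup.event_supports(graph, recnum, 1)
        assert all(f == 1 for f in table.composite.values())


class TestThresholdFilter:
    def _table(self, supports):
        return sup.SupportTable(supports, {}, 2)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            sup.filter_by_threshold([], self._table({}), 1.5)

    def test_threshold_filtering(self):
        e1 = EventRecord("D", "u", ("x",))
        e2 = EventRecord("T", "u", ("x", "y"))
        table = self._table({e1: Fraction(1), e2: Fraction(1, 2)})
        events = [e1, e2]
        assert sup.filter_by_threshold(events, table, 0.0) == [e1, e2]
        assert sup.filter_by_threshold(events, table, 0.7) == [e1]
        assert sup.filter_by_threshold(events, table, 0.5) == [e1, e2]
        assert sup.filter_by_threshold(events, table, 1.0) == [e1]
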