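import pytest

import dtlpareto as dl
from dtlpareto import events as ev
from dtlpareto.events import (EventRecord, Reconciliation,
                              ReconciliationError, atomic_records)


class TestVectorsAndCosts:
    @pytest.mark.parametrize("etype,vec", [
        (ev.TL, (0, 1, 1)), (ev.SL, (0, 0, 1)), (ev.S, (0, 0, 0)),
        (ev.C, (0, 0, 0)), (ev.EMPTY, (0, 0, 0)), (ev.D, (1, 0, 0)),
        (ev.T, (0, 1, 0)),
    ])
    def test_event_vectors(self, etype, vec):
        assert ev.event_vector(etype) == vec

    @pytest.mark.parametrize("v,w,rel", [
        ((0, 0, 0), (1, 2, 4), "strictly_less"),
        ((1, 1, 5), (1, 2, 4), "incomparable"),
        ((0, 4, 0), (2, 4, 0), "strictly_less"),
        ((1, 1, 1), (1, 1, 1), "equal"),
        ((2, 4, 0), (0, 4, 0), "strictly_greater"),
    ])
    def test_dominates(self, v, w, rel):
        assert ev.dominates(v, w) == rel

    def test_cost_of(self):
        assert ev.cost_of((0, 4, 0), (1, 1, 1)) == 4
        assert ev.cost_of((0, 0, 0), (5, 7, 9)) == 0
        assert ev.cost_of((1, 2, 4), (2, 3, 1)) == 12
        with pytest.raises(ValueError):
            ev.cost_of((1, 1, 1), (0, 1, 1))


class TestPostlist:
    def test_speciation_two_assignments(self, fig_sp):
        G = dl.parse_gene_tree("((a_A,b_B),(c_C,d_D));")
        u = G.root
        x = fig_sp.nodes["y"]
        alts = ev.postlist(ev.S, u, x, fig_sp)
        u1, u2 = u.children
        x1, x2 = x.children
        assert {frozenset(a) for a in alts} == {
            frozenset({(u1, x1), (u2, x2)}),
            frozenset({(u1, x2), (u2, x1)})}
        # not defined at a gene leaf or off a speciation node
        assert ev.postlist(ev.S, G.nodes["a_A"], x, fig_sp) == []
        assert ev.postlist(ev.S, u, fig_sp.nodes["x@2"], fig_sp) == []

    def test_no_event_crossing(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        u = G.root
        art = fig_sp.nodes["x@2"]
        assert ev.postlist(ev.EMPTY, u, art, fig_sp) == [(u, art.children[0])]
        assert ev.postlist(ev.EMPTY, u, fig_sp.nodes["y"], fig_sp) == []

    def test_transfer_requires_co_timed_partner(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        u = G.root
        r = fig_sp.nodes["r"]  # alone in its slice
        assert ev.postlist(ev.T, u, r, fig_sp) == []
        assert ev.postlist(ev.TL, u, r, fig_sp) == []

    def test_transfer_loss_unions_slice(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        u = G.root
        x = fig_sp.nodes["x"]  # slice 1: {x, C@1, D@1}
        targets = {p[1].name for p in ev.postlist(ev.TL, u, x, fig_sp)}
        assert targets == {"C@1", "D@1"}


class TestReconciliationValidation:
    def test_valid_congruent_style_reconciliation(self, fig_sp):
        G = dl.parse_gene_tree("((a_A,b_B)u,(c_C,d_D)w2)w;")
        # S at r sends u's subtree to the artificial x@2 and w2's to y
        mapping = {
            "w": ("r",), "u": ("x@2", "x"), "w2": ("y",),
            "a_A": ("A",), "b_B": ("B",),
            "c_C": ("C@1", "C"), "d_D": ("D@1", "D"),
        }
        records = dl.validate_reconciliation(mapping, G, fig_sp)
        types = sorted(r.etype for r in records)
        assert types == ["S", "S", "S"]

    def test_transfer_and_losses_annotated(self, cherry_sp):
        G = dl.parse_gene_tree("a_A;")
        rec = Reconciliation({"a_A": ("x", "B", "A")}, G, cherry_sp)
        assert [p.event for p in rec.positions["a_A"]] == [ev.SL, ev.TL, ev.C]
        assert rec.vector() == (0, 1, 2)

    def test_leaf_species_mismatch_rejected(self, cherry_sp):
        G = dl.parse_gene_tree("a_A;")
        with pytest.raises(ReconciliationError, match="ends at"):
            dl.validate_reconciliation({"a_A": ("B",)}, G, cherry_sp)

    def test_consecutive_tl_rejected(self):
        tree = dl.parse_species_tree("((A,B)1,C)2;", "labels")
        sp = dl.subdivide(tree)
        G = dl.parse_gene_tree("a_A;")
        # B -> C -> A at time 0 chains two TLs
        with pytest.raises(ReconciliationError, match="consecutive TL"):
            dl.validate_reconciliation({"a_A": ("B", "C", "A")}, G, sp)
        # a single TL separated by a crossing is fine
        dl.validate_reconciliation({"a_A": ("C@1", "C", "A")}, G, sp)

    def test_repeated_mapping_rejected(self, cherry_sp):
        G = dl.parse_gene_tree("a_A;")
        with pytest.raises(ReconciliationError, match="repeated"):
            dl.validate_reconciliation({"a_A": ("A", "A")}, G, cherry_sp)

    def test_each_pair_advances_gene_or_species(self, fig_sp):
        # operational form of the traversal property behind the recursion:
        # every non-TL transition moves down in the gene tree or in S'
        G = dl.parse_gene_tree("((a_A,b_B)u,(c_C,d_D)w2)w;")
        mapping = {
            "w": ("r",), "u": ("x@2", "x"), "w2": ("y",),
            "a_A": ("A",), "b_B": ("B",),
            "c_C": ("C@1", "C"), "d_D": ("D@1", "D"),
        }
        rec = Reconciliation(mapping, G, fig_sp)
        for uname, poss in rec.positions.items():
            for i, p in enumerate(poss[:-1]):
                if p.event != ev.TL:
                    nxt = fig_sp.nodes[poss[i + 1].x]
                    assert nxt.parent.name == p.x


class TestEventRecords:
    def test_records_collapse_to_species_branches(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_A);")
        # duplication on the artificial node x@2 and on x give the same record
        rec_hi = Reconciliation(
            {"g1": ("x@2",), "a_A": ("x@2", "x", "A"), "b_A": ("x@2", "x", "A")},
            G, fig_sp)
        rec_lo = Reconciliation(
            {"g1": ("x",), "a_A": ("x", "A"), "b_A": ("x", "A")}, G, fig_sp)
        d_hi = [r for r in rec_hi.records() if r.etype == ev.D]
        d_lo = [r for r in rec_lo.records() if r.etype == ev.D]
        assert d_hi == d_lo == [EventRecord(ev.D, "g1", ("x",))]

    def test_atomic_decomposition(self, fig_species):
        assert atomic_records(EventRecord(ev.D, "u", ("x",)), fig_species) \
            == [EventRecord(ev.D, None, ("x",))]
        assert atomic_records(EventRecord(ev.T, "u", ("x", "y")), fig_species) \
            == [EventRecord(ev.T, None, ("x", "y"))]
        # SL at x surviving towards A loses the B branch
        assert atomic_records(EventRecord(ev.SL, "u", ("x", "A")),
                              fig_species) == [EventRecord("L", None, ("B",))]
        assert atomic_records(EventRecord(ev.TL, "u", ("x", "y")),
                              fig_species) == [
            EventRecord(ev.T, None, ("x", "y")), EventRecord("L", None, ("x",))]
        assert atomic_records(EventRecord(ev.S, "u", ("x",)), fig_species) == []

    def test_vector_matches_event_sum(self, cherry_sp):
        G = dl.parse_gene_tree("a_A;")
        rec = Reconciliation({"a_A": ("x", "B", "A")}, G, cherry_sp)
        total = (0, 0, 0)
        for poss in rec.positions.values():
            for p in poss:
                v = ev.event_vector(p.event)
                total = tuple(a + b for a, b in zip(total, v))
        assert total == rec.vector()


class TestCanonicalForm:
    def test_leading_crossing_is_not_canonical(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        low = Reconciliation(
            {"g1": ("x",), "a_A": ("A",), "b_B": ("B",)}, G, fig_sp)
        padded = Reconciliation(
            {"g1": ("x@2", "x"), "a_A": ("A",), "b_B": ("B",)}, G, fig_sp)
        assert dl.is_canonical(low)
        assert not dl.is_canonical(padded)

    def test_slidable_duplication_is_not_canonical(self, fig_sp):
        G = dl.parse_gene_tree("(a_A,b_A);")
        high = Reconciliation(
            {"g1": ("x@2",), "a_A": ("x@2", "x", "A"), "b_A": ("x@2", "x", "A")},
            G, fig_sp)
        low = Reconciliation(
            {"g1": ("x",), "a_A": ("x", "A"), "b_A": ("x", "A")}, G, fig_sp)
        lowest = Reconciliation(
            {"g1": ("A",), "a_A": ("A",), "b_A": ("A",)}, G, fig_sp)
        # the D at the artificial x@2 shifts down to x: same species-level
        # events one slice lower, so the high placement is not canonical
        assert not dl.is_canonical(high)
        # at the speciation node x the D is pinned (moving it into a child
        # branch would trade the SL losses for a lossless class)
        assert dl.is_canonical(low)
        assert dl.is_canonical(lowest)

    def test_blocked_tl_chain_is_canonical(self):
        # TL, crossing, TL: shifting the first TL down would chain two TLs
        tree = dl.parse_species_tree("((A,C)1,(B,D)2)3;", "labels")
        sp = dl.subdivide(tree)
        G = dl.parse_gene_tree("g1_A;")
        rec = Reconciliation({"g1_A": ("B@1", "D@1", "D", "A")}, G, sp)
        events = [p.event for p in rec.positions["g1_A"]]
        assert events == [ev.TL, ev.EMPTY, ev.TL, ev.C]
        assert dl.is_canonical(rec)
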