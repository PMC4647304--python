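import pytest

import dtlpareto as dl
from dtlpareto import dp
from dtlpareto.events import cost_of
from dtlpareto.pareto import is_pareto_list, pareto_filter

from helpers import brute_front, group_by_start, oracle_instances


class TestHandExamples:
    def test_single_leaf_against_cherry(self, cherry_sp):
        G = dl.parse_gene_tree("a_A;")
        m = dl.compute_pareto_matrix(G, cherry_sp)
        assert m.final["a_A", "A"] == ((0, 0, 0),)
        assert m.final["a_A", "B"] == ((0, 1, 1),)   # TL then C
        # SL towards A; the transfer-and-lose route (0,1,2) is dominated
        assert m.final["a_A", "x"] == ((0, 0, 1),)
        assert m.root_front == ((0, 0, 0),)

    def test_congruent_cherry(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        m = dl.compute_pareto_matrix(G, cherry_sp)
        # speciation wins; D route (1,0,2) and swapped-S route (0,2,2) dominated
        assert m.final["g1", "x"] == ((0, 0, 0),)
        assert m.root_front == ((0, 0, 0),)

    def test_all_lists_are_pareto(self, fig_sp):
        G = dl.parse_gene_tree("((a_A,b_B),(c_C,d_A));")
        m = dl.compute_pareto_matrix(G, fig_sp)
        for lst in list(m.final.values()) + list(m.phase1.values()):
            assert is_pareto_list(lst)


class TestBestTriplets:
    def test_pair_slice_excludes_own_node(self):
        lists = {"x": ((0, 0, 0),), "z": ((0, 0, 1),)}
        assert dp.best_triplets(lists, "x") == ((0, 0, 1),)
        assert dp.best_triplets(lists, "z") == ((0, 0, 0),)

    def test_singleton_slice_is_empty(self):
        assert dp.best_triplets({"x": ((0, 0, 0),)}, "x") == ()

    def test_exclusion_happens_before_filtering(self):
        # (0,0,0) lives only at x and dominates z1's vector; excluding x must
        # still leave z1's vector available as a receiver
        lists = {"x": ((0, 0, 0),), "z1": ((0, 0, 1),), "z2": ((0, 0, 0),)}
        assert dp.best_triplets(lists, "x") == ((0, 0, 0),)
        assert dp.best_triplets(lists, "z2") == ((0, 0, 0),)
        assert dp.best_triplets(lists, "z1") == ((0, 0, 0),)
        lists2 = {"x": ((0, 0, 0),), "z1": ((0, 0, 1),)}
        assert dp.best_triplets(lists2, "x") == ((0, 0, 1),)


class TestMinCost:
    def test_congruent_cherry_costs_zero(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,b_B);")
        total, _ = dp.min_cost(G, cherry_sp, (2, 3, 1))
        assert total == 0

    def test_two_copies_duplicate_at_leaf(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,a2_A);")
        total, table = dp.min_cost(G, cherry_sp, (2, 3, 1))
        assert total == 2  # one D at leaf A beats any transfer or SL route
        assert table["g1", "A"] == 2

    @pytest.mark.parametrize("seed", [2, 5, 11])
    def test_consistent_with_pareto_front(self, seed):
        from helpers import random_instance
        _, sp, G = random_instance(seed)
        costs = (2.0, 3.0, 1.0)
        total, table = dp.min_cost(G, sp, costs)
        m = dl.compute_pareto_matrix(G, sp)
        assert min(cost_of(v, costs) for v in m.root_front) \
            == pytest.approx(total)
        for (u, x), lst in m.final.items():
            if lst:
                assert min(cost_of(v, costs) for v in lst) \
                    == pytest.approx(table[u, x])


class TestEpsilonMode:
    def test_epsilon_zero_keeps_min_cost_front(self, cherry_sp):
        G = dl.parse_gene_tree("(a_A,a2_A);")
        costs = (2.0, 3.0, 1.0)
        m0 = dl.compute_pareto_matrix(
            G, cherry_sp, dp.DPOptions("epsilon", costs, 0.0))
        total, _ = dp.min_cost(G, cherry_sp, costs)
        assert all(cost_of(v, costs) == pytest.approx(total)
                   for v in m0.root_front)

    def test_epsilon_infinite_equals_pareto_mode(self, fig_sp):
        G = dl.parse_gene_tree("((a_A,b_B),(c_C,d_A));")
        mp = dl.compute_pareto_matrix(G, fig_sp)
        me = dl.compute_pareto_matrix(
            G, fig_sp, dp.DPOptions("epsilon", (2.0, 3.0, 1.0), 1e12))
        assert mp.root_front == me.root_front
        assert mp.final == me.final

    def test_requires_costs(self):
        with pytest.raises(ValueError):
            dp.DPOptions(mode="epsilon")


class TestStarFilter:
    def test_transfer_return_signature_removed(self):
        assert dp.epsilon_star_filter([(0, 2, 2), (1, 1, 2)]) == ((1, 1, 2),)

    def test_incomparable_triple_unchanged(self):
        vs = [(1, 1, 5), (0, 3, 2), (1, 2, 4)]
        assert dp.epsilon_star_filter(vs) == tuple(sorted(vs))

    def test_singleton_and_idempotence(self):
        assert dp.epsilon_star_filter([(3, 1, 4)]) == ((3, 1, 4),)
        once = dp.epsilon_star_filter([(0, 2, 0), (1, 1, 0), (2, 0, 5)])
        assert dp.epsilon_star_filter(once) == once


class TestOracleEquivalence:
    """Theorem-level checks of the DP against exhaustive enumeration (a
    handful here; the full battery lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", [1, 3, 4, 6, 8])
    def test_root_fronts_match_bruteforce(self, seed):
        for _, _, sp, G, recs in oracle_instances(1, start_seed=seed):
            m = dl.compute_pareto_matrix(G, sp)
            assert m.root_front == brute_front(recs)
            by_x = group_by_start(recs, G.root.name)
            for x in sp.postorder():
                assert m.final[G.root.name, x.name] \
                    == pareto_filter(by_x.get(x.name, []))


class TestScaling:
    def test_moderate_instance_completes(self):
        # a smoke check that the DP scales beyond oracle sizes
        import numpy as np
        from dtlpareto import simulate as sim
        from helpers import random_gene_tree
        rng = np.random.default_rng(99)
        S = sim.random_dated_species_tree(12, rng)
        G = random_gene_tree(rng, sorted(S.species_set), 20)
        m = dl.compute_pareto_matrix(G, dl.subdivide(S))
        assert m.root_front
        assert all(is_pareto_list(l) for l in m.final.values())
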