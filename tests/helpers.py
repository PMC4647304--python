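"""Shared test utilities: random instances and brute-force oracle wrappers."""

from __future__ import annotations

from collections import Counter
from typing import List, Tuple

import numpy as np

import dtlpareto as dl
from dtlpareto import simulate as sim
from dtlpareto.pareto import pareto_filter


def random_gene_tree(rng: np.random.Generator, species: List[str],
                     n_leaves: int) -> dl.GeneTree:
    """Random binary gene tree over leaves sampled (with repetition) from
    the given species, built by uniform random joins."""
    items = [f"g{i}_{rng.choice(species)}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return dl.parse_gene_tree(items[0] + ";", sep="_")


def random_instance(seed: int, max_species: int = 5, max_genes: int = 4):
    """A (species tree, subdivision, gene tree) triple small enough for the
    exhaustive oracle."""
    rng = np.random.default_rng(seed)
    n_s = int(rng.choice([3, 3, 4, 4, max_species]))
    n_g = int(rng.choice([2, 3, 3, max_genes]))
    species_tree = sim.random_dated_species_tree(n_s, rng)
    sp = dl.subdivide(species_tree)
    gene_tree = random_gene_tree(rng, sorted(species_tree.species_set), n_g)
    return species_tree, sp, gene_tree


def brute_front(recs) -> Tuple:
    return pareto_filter(r.vector() for r in recs)


def group_by_start(recs, root_name: str):
    """Vectors of enumerated reconciliations grouped by the root's first
    S' placement."""
    by_x = {}
    for r in recs:
        by_x.setdefault(r.mapping[root_name][0], []).append(r.vector())
    return by_x


def record_distance(a: dl.Reconciliation, b: dl.Reconciliation) -> int:
    """Symmetric multiset distance between the event records of two
    reconciliations."""
    ca, cb = Counter(a.records()), Counter(b.records())
    return sum((ca - cb).values()) + sum((cb - ca).values())


def oracle_instances(n_wanted: int, start_seed: int = 1,
                     max_count: int = 20000):
    """Yield (seed, species tree, S', gene tree, enumerated reconciliations)
    for the first ``n_wanted`` seeds whose enumeration fits the size guard."""
    produced = 0
    seed = start_seed
    while produced < n_wanted:
        species_tree, sp, gene_tree = random_instance(seed)
        seed += 1
        try:
            recs = sim.enumerate_reconciliations_bruteforce(
                gene_tree, sp, max_count=max_count)
        except sim.BruteForceLimit:
            continue
        produced += 1
        yield seed - 1, species_tree, sp, gene_tree, recs


def subtree_gene_tree(gene_tree: dl.GeneTree, node_name: str) -> dl.GeneTree:
    """The gene subtree rooted at a node, as a standalone GeneTree."""
    node = gene_tree.nodes[node_name]

    def fmt(n):
        if n.is_leaf:
            return n.name
        return "(" + ",".join(fmt(c) for c in n.children) + ")" + n.name

    return dl.parse_gene_tree(fmt(node) + ";", sep="_")
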