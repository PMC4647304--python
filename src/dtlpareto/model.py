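"""Model/Results interface over the reconciliation machinery.

``DTLModel`` holds a (gene tree, dated species tree) pair; ``fit`` runs one of
the reconciliation strategies and returns a ``DTLResults`` carrying the Pareto
front, the retained event count vectors, the reconciliation graph, the exact
solution-space size, per-event supports, the median reconciliation and a
printable summary.

Strategies
----------
single
    Parsimonious reconciliations for one cost vector (a degenerate ratio
    range pinned at its ratios).
range
    Parsimonious reconciliations for at least one cost vector inside a ratio
    box around the input costs (percent variation of delta/tau and
    lambda/delta, or explicit bounds).
epsilon
    Pareto-optimal reconciliations within an over-cost ``epsilon`` of the
    minimum; by default epsilon = |tau - delta|, letting duplications trade
    against transfers.
epsilon-star
    As ``epsilon``, additionally dropping count vectors that are only optimal
    when transfers are dramatically cheaper than duplications (spurious
    transfer-and-return chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from . import costspace, dp, recgraph, supports as sup
from .events import EventRecord, Reconciliation, atomic_records
from .trees import (DatedSpeciesTree, GeneTree, SubdividedTree,
                    parse_gene_tree, parse_species_tree, read_leaf_map,
                    subdivide)

__all__ = ["DTLModel", "DTLResults", "STRATEGIES"]

STRATEGIES = ("single", "range", "epsilon", "epsilon-star")


class DTLModel:
    """A gene family to be reconciled against a dated species tree."""

    def __init__(self, gene_tree: GeneTree, species_tree: DatedSpeciesTree):
        if not gene_tree.species_set <= species_tree.species_set:
            raise ValueError(
                "gene-tree species must be a subset of the species tree's")
        self.gene_tree = gene_tree
        self.species_tree = species_tree
        self.sp: SubdividedTree = subdivide(species_tree)

    @classmethod
    def from_newick(cls, gene_newick: str, species_newick: str,
                    dating="labels", sep: Optional[str] = "_",
                    leaf_map=None) -> "DTLModel":
        species = parse_species_tree(species_newick, dating)
        gene = parse_gene_tree(gene_newick, species.species_set, sep, leaf_map)
        return cls(gene, species)

    @classmethod
    def from_files(cls, gene_path: str, species_path: str, dating="labels",
                   sep: Optional[str] = "_",
                   leaf_map_path: Optional[str] = None) -> "DTLModel":
        with open(gene_path) as fh:
            gene_newick = fh.read()
        with open(species_path) as fh:
            species_newick = fh.read()
        leaf_map = read_leaf_map(leaf_map_path) if leaf_map_path else None
        return cls.from_newick(gene_newick, species_newick, dating, sep,
                               leaf_map)

    def fit(self, strategy: str = "range",
            costs: Sequence[float] = (2.0, 3.0, 1.0),
            range_pct: Tuple[float, float] = (40.0, 40.0),
            range_bounds: Optional[Tuple[Tuple[float, float],
                                         Tuple[float, float]]] = None,
            epsilon: Optional[float] = None) -> "DTLResults":
        """Run a reconciliation strategy; see the module docstring."""
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; "
                             f"choose from {STRATEGIES}")
        costs = costspace.CostVector.make(costs)
        ratio_range = None
        eps_used = None

        if strategy in ("single", "range"):
            matrix = dp.compute_pareto_matrix(self.gene_tree, self.sp,
                                              dp.DPOptions(mode="pareto"))
            if strategy == "single":
                ratio_range = costspace.RatioRange.point(costs)
            elif range_bounds is not None:
                ratio_range = costspace.range_from_bounds(*range_bounds)
            else:
                ratio_range = costspace.range_around(costs, *range_pct)
            retained = costspace.compute_pars(matrix.root_front, ratio_range)
        else:
            eps_used = (abs(costs.tau - costs.delta)
                        if epsilon is None else float(epsilon))
            matrix = dp.compute_pareto_matrix(
                self.gene_tree, self.sp,
                dp.DPOptions(mode="epsilon", costs=costs, epsilon=eps_used))
            retained = matrix.root_front
            if strategy == "epsilon-star":
                retained = dp.epsilon_star_filter(retained)

        graph = recgraph.build_graph(self.gene_tree, self.sp, matrix, retained)
        scores = sup.compute_scores(graph)
        n = sum(scores[id(r)] for r in graph.roots)
        recnum = sup.compute_recnum(graph, scores)
        table = sup.event_supports(graph, recnum, n)
        median = sup.median_reconciliation(graph, table)
        return DTLResults(model=self, strategy=strategy, costs=costs,
                          ratio_range=ratio_range, epsilon=eps_used,
                          matrix=matrix, retained=retained, graph=graph,
                          n_reconciliations=n, supports=table, median=median)


@dataclass
class DTLResults:
    """Results of one reconciliation strategy on one gene family."""

    model: DTLModel
    strategy: str
    costs: costspace.CostVector
    ratio_range: Optional[costspace.RatioRange]
    epsilon: Optional[float]
    matrix: dp.ParetoMatrix
    retained: Tuple
    graph: recgraph.ReconciliationGraph
    n_reconciliations: int
    supports: sup.SupportTable
    median: Reconciliation

    @property
    def pareto_front(self):
        return self.matrix.root_front

    @property
    def min_cost(self) -> float:
        from .events import cost_of
        return min(cost_of(v, self.costs) for v in self.pareto_front)

    def predicted_events(self, threshold: float = 0.0) -> List[EventRecord]:
        """Median-reconciliation events with support >= threshold."""
        return sup.filter_by_threshold(self.median.records(), self.supports,
                                       threshold)

    def predicted_atomic(self, threshold: float = 0.0):
        """Atomic D/T/L multiset of the threshold-filtered median events."""
        from collections import Counter
        st = self.model.species_tree
        out: Counter = Counter()
        for rec in self.predicted_events(threshold):
            for a in atomic_records(rec, st):
                out[a] += 1
        return out

    def summary(self) -> str:
        lines = [
            "DTL reconciliation results",
            "==========================",
            f"strategy:            {self.strategy}",
            f"costs (d, t, l):     ({self.costs.delta:g}, {self.costs.tau:g},"
            f" {self.costs.lam:g})",
        ]
        if self.ratio_range is not None:
            lines.append(f"ratio range:         "
                         f"[{_fmt3(self.ratio_range.r_m)};"
                         f" {_fmt3(self.ratio_range.r_M)}]")
        if self.epsilon is not None:
            lines.append(f"over-cost epsilon:   {self.epsilon:g}")
        lines += [
            f"gene leaves:         {len(self.model.gene_tree.leaves)}",
            f"species leaves:      {len(self.model.species_tree.leaves)}",
            f"Pareto front (root): {list(self.pareto_front)}",
            f"retained vectors:    {list(self.retained)}",
            f"minimum cost:        {self.min_cost:g}",
            f"reconciliations:     {self.n_reconciliations}",
            "",
            "median reconciliation events (support):",
        ]
        med_recs = self.median.records()
        for rec in med_recs:
            f = self.supports.composite.get(rec, Fraction(1))
            lines.append(f"  {rec.etype:<3} {rec.gene:<10}"
                         f" {'|'.join(rec.loc):<16} {float(f):.4f}")
        return "\n".join(lines)

    def plot_supports(self, ax=None):
        """Bar plot of composite event supports (matplotlib, optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        items = sorted(self.supports.composite.items())
        labels = [f"{r.etype}:{r.gene}@{'|'.join(r.loc)}" for r, _ in items]
        ax.bar(range(len(items)), [float(f) for _, f in items])
        ax.set_xticks(range(len(items)))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_ylabel("support f(e)")
        ax.set_ylim(0, 1.05)
        return ax


def _fmt3(t) -> str:
    return "(" + ", ".join(f"{v:.4g}" for v in t) + ")"
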