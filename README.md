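# dtlpareto

Parsimonious reconciliation of gene trees with dated species trees under the
DTL model (duplication, transfer, loss), with **event supports** computed over
the full space of optimal and near-optimal reconciliations.

## The problem

A gene family's history often disagrees with the history of the species that
carry it: genes duplicate (D), are transferred horizontally (T) and are lost
(L). A *reconciliation* embeds a rooted gene tree `G` into a dated species
tree `S`, annotating the discrepancies with events. Parsimony picks the
reconciliation minimizing the total cost `d·δ + t·τ + l·λ` for an event cost
vector `c = (δ, τ, λ)` — but the right costs are rarely known, many
reconciliations tie, and the input trees carry errors. Single "best"
reconciliations therefore predict many spurious events.

`dtlpareto` instead represents **all** reconciliations that are optimal for a
whole region of cost space (or within an over-cost tolerance ε of optimal) in
one polynomial-size *reconciliation graph*, and scores each predicted event
`e` by its support

```
f(e) = (number of represented reconciliations containing e) / N ,
```

where `N` is the (possibly astronomically large) number of represented
reconciliations, counted exactly from the graph. It also extracts the *median
reconciliation* — the represented reconciliation minimizing the summed
event-set distance to all others — whose events, filtered at a support
threshold, are markedly more reliable than those of an arbitrary optimum.

The machinery:

* a dynamic program over the *dated subdivision* `S′` of the species tree
  (artificial nodes cut every branch at every internal node time, so that
  transfers are constrained to contemporaneous donor–receiver pairs) which
  computes, for every gene node `u` and `S′` node `x`, the **Pareto front**
  `C(u, x)` of achievable event-count vectors `(d, t, l)`;
* a 2-variable LP feasibility filter retaining the vectors that attain the
  minimum cost for at least one cost vector inside a **ratio cost range**
  `r(c) = (λ/τ, δ/τ, λ/δ)` (strategy `range`), or a per-mapping cost pruning
  retaining **ε-Pareto-optimal** vectors (strategies `epsilon` and
  `epsilon-star`, the latter additionally discarding transfer-and-return
  signatures);
* the reconciliation graph over the retained vectors, restricted to
  *canonical* reconciliations (every event placed as low as possible within
  its species branch, so each species-level scenario is represented exactly
  once), from which exact counts, supports and the median follow by two graph
  traversals.

A discrete-time birth–death simulator of gene family histories along a dated
phylogeny, an exhaustive small-instance oracle, and an FP/FN evaluation
metric complete the package.

## Worked example

Species tree `((A,B),(C,D))` with internal times 1, 2, 3 (leaves at 0); gene
tree `((a_A,(b_B,c_C)),d_D)` — `b` and `c` are sisters although `B` and `C`
sit in different species clades.

```python
import dtlpareto as dl

model = dl.DTLModel.from_newick(
    "((a_A,(b_B,c_C)),d_D);",       # leaf species after the "_"
    "((A,B)1,(C,D)2)3;",            # internal labels are time ranks
)
res = model.fit(strategy="range", costs=(2, 3, 1), range_pct=(40, 40))
print(res.summary())
```

prints

```
DTL reconciliation results
==========================
strategy:            range
costs (d, t, l):     (2, 3, 1)
ratio range:         [(0.12, 0.4, 0.3); (0.6533, 0.9333, 0.7)]
gene leaves:         4
species leaves:      4
Pareto front (root): [(0, 1, 1), (0, 2, 0), (2, 0, 6)]
retained vectors:    [(0, 1, 1)]
minimum cost:        4
reconciliations:     1

median reconciliation events (support):
  T   g3         B|C              1.0000
  S   g2         t1               1.0000
  SL  d_D        t2|D             1.0000
  S   g1         t3               1.0000
```

Read this as: three Pareto-optimal event-count profiles exist — one transfer
plus one loss, two transfers, or two duplications plus six losses — but only
`(0, 1, 1)` is parsimonious somewhere inside the ±40 % cost-ratio box around
`(2, 3, 1)`; that profile is realized by exactly one reconciliation
(`N = 1`), so every event has support 1.0. The history it proposes: the gene
tracks both speciations, `c`'s lineage arrives in `C` by a transfer from
branch `B` (support column: `T … B|C`), and `d_D`'s lineage loses its copy on
the `C` side of speciation `t2`.

The same pipeline from a shell:

```bash
dtlpareto simulate --species 8 --seed 7 --n-families 5 -o fam/
dtlpareto reconcile -s fam/species.nwk -g fam/family001.nwk \
    --strategy epsilon --costs 2,3,1 -o out/
dtlpareto evaluate --pred out/events.tsv --truth fam/family001.truth.tsv \
    --thresholds 0:1:0.1 -o report.tsv
```

`reconcile` writes per-event supports (`supports.tsv`), the median
reconciliation (`median.txt`) and its atomic D/T/L events with supports
(`events.tsv`); `evaluate` sweeps the support threshold and reports mean
false positives and false negatives against the simulated truth.

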