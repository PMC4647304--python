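# Methods

## The reconciliation model

A species tree `S` is rooted, binary and *dated*: leaves at time 0, internal
nodes at pairwise-distinct integer ranks `1..n−1` decreasing towards the
leaves. Real-valued node ages carry no extra information for this model and
are converted to ranks (ties broken by post-order index). The *dated
subdivision* `S′` inserts a single-child artificial node on every branch at
every internal time it crosses, so every edge of `S′` spans exactly one time
slice and `V_t(S′)` — the nodes at time `t` — identifies the branches alive
in slice `t`.

A reconciliation maps each gene-tree node `u` to an ordered sequence of `S′`
nodes. Each position carries exactly one event, determined by the sequence
itself:

* final position — `C` (contemporary) for a gene leaf at the matching species
  leaf, else a birth event: `S` (speciation, children follow the two species
  children), `D` (duplication, both children stay), or `T` (transfer, one
  child stays, the other jumps to a co-timed node);
* non-final position — `SL` (speciation, lost on one side), `TL` (transfer
  whose donor copy is lost), or the no-event crossing of an artificial node.

Losses never occur alone (an unconstrained duplication-loss would make the
solution space infinite) and two consecutive `TL`s are forbidden for the same
reason. Transfers — `T` and `TL` — are only allowed between co-timed nodes,
which is what makes every inferred transfer time-consistent. Events "above"
the species root are not modeled: the gene root maps to some node of `S′`.

Event count vectors `(d, t, l)` add componentwise (`⊕`) and pair with a cost
vector `c = (δ, τ, λ)` by dot product (`⊗`). A reconciliation is
*Pareto-optimal* if no other reconciliation has a componentwise strictly
smaller vector; every reconciliation that is parsimonious for some positive
`c` is Pareto-optimal, but not conversely.

## The Pareto dynamic program (`dp`)

`C(u, x)` is the Pareto front of vectors of reconciliations of the gene
subtree at `u` whose first mapping is `x`. Gene nodes are processed in
post-order and `S′` nodes in increasing time; within one slice the update is
two-phased: phase 1 fills the TL-free lists from the `C`/crossing/`SL`/`S`/
`D`/`T` clauses, phase 2 adds `TL` options `v(TL) ⊕ w` where `w` ranges over
the TL-free fronts of co-timed nodes, so no `TL` can chain onto another. The
TL-free (phase-1) lists are retained: the graph builder needs them for the
same reason.

Receiver options for `T`/`TL` at `(u, x)` come from the Pareto front of the
union of the co-timed lists excluding `x` itself. The exclusion is applied to
the *unfiltered* union (tracking per-vector contributor sets): filtering
first could discard a receiver vector dominated only by `x`'s own list, which
is not available as a receiver.

The algebra lives in `pareto`: fronts are kept as lexicographically sorted,
duplicate-free tuples, so structural equality is front equality; a dominating
vector always sorts before the vectors it dominates, which gives a single
sorted sweep for filtering and an `O(k²)` pairwise-sum combine.

Two scalar quantities ride along: a `(min, +)` variant of the same recursion
gives the minimum cost `cost_m(u, x, c)` per mapping and the global optimum.
In **epsilon mode** every list is pruned to vectors with
`v ⊗ c ≤ cost_m(u, x, c) + ε`; because restrictions of ε-Pareto-optimal
reconciliations are themselves ε-Pareto-optimal at their own mappings, local
pruning loses nothing, and the root front (cost-filtered once more, then
Pareto-filtered) is exactly the set of ε-Pareto-optimal vectors. `ε = 0`
retains the parsimonious vectors; `ε = ∞` reproduces plain Pareto mode.

## Cost space (`costspace`)

Parsimony depends only on cost ratios, summarized as
`r(c) = (λ/τ, δ/τ, λ/δ)`. A ratio box `[r_m; r_M]` is built either by varying
`δ/τ` and `λ/δ` by a percentage around an input vector (the `λ/τ` bounds are
the products of the extreme bounds of the other two) or from explicit bounds
on `λ/δ` and `τ/δ`. With `τ` normalized to 1, a front vector `v` is retained
iff the system `v ⊗ (δ, 1, λ) ≤ v′ ⊗ (δ, 1, λ)` for all front competitors
`v′`, subject to the box (the `λ/δ` bounds rewritten linearly), is feasible —
a 2-variable LP solved with HiGHS through `scipy.optimize.linprog`.
Inequalities are weak (parsimony means *attaining* the minimum), positivity
is enforced as `δ, λ ≥ 1e−9`, and comparisons carry a `1e−9` slack.

Cost vectors can also be derived from observed event counts as
`cost(e) = log(n_tot / n_e)` — rare events become expensive. The log base is
natural by default (the choice only scales all three costs, which parsimony
ignores) and configurable.

## Strategies (`model`)

* `single` — degenerate box pinned at `r(c)`: all parsimonious
  reconciliations for one cost vector.
* `range` — the LP filter over a ratio box (default ±40 % on `δ/τ`, `λ/δ`).
* `epsilon` — ε-Pareto-optimal vectors; the default over-cost is
  `ε = |τ − δ|`, letting a duplication trade against a transfer, since those
  are the two event types that can explain the same topological discrepancy.
* `epsilon-star` — additionally drops any vector `(d, t, l)` for which some
  other retained `(d′, t′, l′)` has `l′ ≤ l`, `t′ ≤ t` and `d′+t′ ≤ d+t`.
  Such vectors are only ever optimal when transfers are drastically cheaper
  than duplications — the signature of spurious transfer-and-return chains.
  The condition is a strict Pareto filter in the coordinates `(t, l, d+t)`,
  hence order-independent. It is applied to the root front; an optional
  in-DP variant prunes every list *and* the root front and is checked to
  yield the identical root list (per-mapping pruning is provably lossless
  when `δ ≤ τ`, since star-domination then implies cost-domination).

`DTLModel(gene_tree, species_tree).fit(strategy=...)` returns a `DTLResults`
carrying the front, the retained vectors, the graph, the exact count, the
support table, the median reconciliation and a `summary()`.

## The reconciliation graph (`recgraph`)

Mapping nodes `(u, x, v)` alternate with event nodes; an event node's vector
identity `v(parent) = v(event) ⊕ Σ v(children)` ties the graph to the DP
lists, and every *full subtree* (one event child per mapping node, all
children of each event node) depicts one reconciliation. The builder
backtracks from the root mappings whose vectors are retained, matching every
decomposition against the stored fronts — `TL` children against the TL-free
phase lists — and memoizing on the node key, so each mapping node occurs
once.

Only **canonical** reconciliations are represented, one per class of
reconciliations with identical species-level events (placements of `D`, `T`,
`TL` can slide between the artificial nodes of a branch without changing
anything observable). Canonical means every event sits as low as possible:

* the root sequence must not begin with a no-event crossing (dropping it
  gives the same events from a lower starting point);
* no `D`/`T`/`TL` event with all-artificial endpoints may have a forward
  same-slice closure that is entirely *unpinned* and exits only through
  no-event crossings. The closure collects the later events of the lineages
  an event spawns while they remain in the slice; "pinned" means an endpoint
  is a speciation node or leaf (sliding would change the species location),
  and a `TL` whose continuation is a crossing followed immediately by another
  `TL` is also immovable — the one-slice shift would chain two `TL`s, which
  the model forbids. An unpinned, unblocked closure shifts down wholesale, so
  the placement is not the lowest one.

These are correlated constraints across a mapping node's children, which a
plain `(u, x, v)` node cannot express. Mapping nodes therefore carry an
*entry tag* (first event unrestricted / not-a-crossing / exactly-a-crossing,
plus a no-leading-`TL` flag for `TL` continuations), and slidable event nodes
split their children into disjoint tag combinations covering exactly the
canonical choices; deduplication is per `(u, x, v, tag)`. The brute-force
oracle (`simulate.enumerate_reconciliations_bruteforce` +
`events.is_canonical`) implements the same definition independently on
explicit reconciliations, and the test suite checks on every oracle instance
that each species-level class contains exactly one canonical member and that
the graph depicts exactly those.

## Supports and the median (`supports`)

`score(z)` (post-order: product over an event node's children, sum over a
mapping node's event children) counts completable sub-solutions; `recNum(z)`
(pre-order: roots get their score, mapping nodes sum their parents, event
nodes split the parent's count by score ratio — always an exact integer
division) counts the represented reconciliations containing `z`. Counts use
Python's arbitrary-precision integers; supports are exact `Fraction`s
`recNum/N`. Event identities are species-level (type, gene node, species
locations via the branch back-map), so slice-shifted placements and different
count-vector contexts of one event pool their frequencies. `C` events and
crossings carry no D/T/L content and are excluded from the table by default;
atomic rows (gene-anonymous D, T, L records) report summed supports, i.e.
expected multiplicities.

The median reconciliation maximizes `Σ (2·f(e) − 1)` over its events — an
equivalent reformulation of minimizing the summed symmetric event-set
distance to all represented reconciliations — via one more max-weight
traversal (mapping node: best event child; event node: own weight plus
children), with deterministic tie-breaking by the stored child order (events
ordered S, D, T, SL, TL, crossing, C; children by node name; vectors
lexicographically). If a full subtree ever contained the same event identity
twice (a pathological transfer round-trip), occurrences would be scored
independently; a warning is emitted in that case.

## The simulator (`simulate`)

`simulate_history` is a discrete-time analogue of a gene birth–death process
along the dated phylogeny: one gene copy enters at the species root; per
slice segment a copy undergoes at most one event — duplication, transfer to a
uniformly chosen co-timed other branch, or loss — with competing-risk
probability `1 − exp(−rate · span)` split proportionally to the rates.
Defaults are the study conditions this generator emulates: loss rate drawn
from `[0.001, 0.0018]` events/gene/My, birth/loss ratio from `[0.5, 1.1]`,
duplication share of births from `[0.7, 1]`. Because time ranks are ordinal,
a `slice_span_my` parameter (default 100 My per rank step) sets how much
evolution one slice holds; the default makes desk-scale trees (~8 taxa)
produce families with a handful of D/T/L events each, the same qualitative
regime as the original 37-taxon simulations (on the order of 4 duplications,
1 transfer and 8 losses per family).

Extinct subtrees are pruned from the returned gene tree. Events inside a
fully extinct subtree are dropped and one loss is recorded at the pruning
point: a speciation with one dead side yields a loss on that child branch, a
duplication with one dead copy a loss on its own branch, a transfer with a
dead receiver (or donor) copy a loss on the receiver (donor) branch. A
transfer whose receiver lineage died leaves no trace in the gene tree, so its
`T` record is an unavoidable false negative for any inference method — kept
deliberately, as real histories have the same property.

What the simulator does **not** emulate: continuous time within slices,
multiple events per copy per slice, sequence evolution and gene-tree
inference error (a leaf-label swap perturbation is available instead), and
rate variation across branches. Accuracy numbers on these histories
therefore speak to the reconciliation machinery under a correctly specified
model, not to errors introduced by tree estimation.

Truth-vs-prediction evaluation compares gene-anonymous atomic records —
`(D, branch)`, `(T, donor, receiver)`, `(L, branch)` — as **multisets**:
`FP = |predicted ∖ truth|`, `FN = |truth ∖ predicted|`, distance `FP + FN`.

## Numerical and testing choices

* Cost comparisons and LP feasibility use absolute tolerance `1e−9`; all
  counting is exact integer/rational arithmetic.
* The exhaustive oracle is guarded to ≤ 7 gene and ≤ 6 species leaves and a
  20 000-reconciliation cap; the acceptance battery uses 50 seeded instances
  with 3–5 species and 2–4 gene leaves (seeds whose enumeration exceeds the
  cap are skipped deterministically), sizes at which enumeration stays in the
  tens of seconds while still exercising transfers across multi-node slices.
  The brute-force median check is restricted to instances with ≤ 300
  represented reconciliations (the distance matrix is quadratic).
* Degenerate inputs: a gene family restricted to one species reconciles by
  duplications at that leaf; a single-leaf gene tree is legal; an empty
  retained-vector set is an error, as is a non-positive cost component.

## Limitations

* Only fully dated (ranked) species trees are supported; partially dated
  trees would need a different subdivision.
* The LP filter decides per-vector feasibility; it does not enumerate cost
  regions or their areas.
* The median minimizes the summed event distance; alternatives (e.g.
  maximizing mean event support) are not implemented.
* Graphs spanning alternative gene- or species-tree topologies are out of
  scope.
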