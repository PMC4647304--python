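"""Species and gene trees: parsing, dating, validation and time-slice subdivision.

The reconciliation model works on a *dated* species tree: a rooted binary tree
whose internal nodes carry pairwise-distinct integer time ranks (leaves are at
time 0, internal nodes at 1..n-1).  The *subdivision* inserts single-child
artificial nodes on every branch crossing an internal time, so that every time
slice is crossed explicitly; transfers are only allowed between nodes in the
same slice, which is what makes the inferred transfers time-consistent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union

import dendropy

__all__ = [
    "TreeError",
    "GeneTree",
    "DatedSpeciesTree",
    "SubdividedTree",
    "SpeciesNode",
    "GeneNode",
    "parse_species_tree",
    "parse_gene_tree",
    "read_leaf_map",
    "subdivide",
]


class TreeError(ValueError):
    """Raised for structurally invalid or inconsistently dated input trees."""


# ---------------------------------------------------------------------------
# node types


class _Node:
    __slots__ = ("name", "parent", "children")

    def __init__(self, name: str):
        self.name = name
        self.parent: Optional["_Node"] = None
        self.children: list = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)

    def postorder(self) -> Iterator["_Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def __repr__(self):  # pragma: no cover - debug aid
        return f"<{type(self).__name__} {self.name}>"


class GeneNode(_Node):
    """Gene-tree node; leaves carry the species label ``species``."""

    __slots__ = ("species",)

    def __init__(self, name: str, species: Optional[str] = None):
        super().__init__(name)
        self.species = species


class SpeciesNode(_Node):
    """Species-tree node with an integer time rank ``time``.

    In a subdivided tree, ``kind`` is one of ``leaf``/``speciation``/
    ``artificial`` and ``s_branch`` names the species-tree node at the bottom
    of the branch this node lies on (the back-map used to collapse
    slice-shifted event placements onto species-tree branches).
    """

    __slots__ = ("time", "kind", "s_branch", "species")

    def __init__(self, name: str, time: int = 0):
        super().__init__(name)
        self.time = time
        self.kind = "leaf"
        self.s_branch = name
        self.species: Optional[str] = None


# ---------------------------------------------------------------------------
# tree containers


class GeneTree:
    """A rooted binary gene tree whose leaves are mapped to species labels."""

    def __init__(self, root: GeneNode):
        self.root = root
        self.nodes = {n.name: n for n in root.postorder()}
        if len(self.nodes) != sum(1 for _ in root.postorder()):
            raise TreeError("duplicate node names in gene tree")
        self._validate()

    def _validate(self) -> None:
        for n in self.postorder():
            if n.children and len(n.children) != 2:
                raise TreeError(f"gene tree is not binary at node {n.name!r}")
            if n.is_leaf and not n.species:
                raise TreeError(f"gene leaf {n.name!r} has no species label")

    def postorder(self) -> Iterator[GeneNode]:
        return self.root.postorder()

    @property
    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def species_set(self) -> set:
        return {n.species for n in self.leaves}

    def __len__(self) -> int:
        return len(self.nodes)

    def newick(self) -> str:
        def fmt(n: GeneNode) -> str:
            if n.is_leaf:
                return n.name
            return "(" + ",".join(fmt(c) for c in n.children) + ")" + n.name

        return fmt(self.root) + ";"


class DatedSpeciesTree:
    """A rooted binary species tree with a strict total order on internal times."""

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes = {n.name: n for n in root.postorder()}
        self._validate()

    def _validate(self) -> None:
        leaves, internals = [], []
        for n in self.postorder():
            if n.children and len(n.children) != 2:
                raise TreeError(f"species tree is not binary at node {n.name!r}")
            (leaves if n.is_leaf else internals).append(n)
        if len({l.name for l in leaves}) != len(leaves):
            raise TreeError("duplicate leaf labels in species tree")
        for l in leaves:
            if l.time != 0:
                raise TreeError(f"leaf {l.name!r} has nonzero time {l.time}")
        times = sorted(n.time for n in internals)
        if times != list(range(1, len(internals) + 1)):
            raise TreeError(
                "internal node times must be the ranks 1..n-1 with no duplicates; "
                f"got {times}"
            )
        for n in internals:
            for c in n.children:
                if c.time >= n.time:
                    raise TreeError(
                        f"time of {c.name!r} ({c.time}) not below its parent "
                        f"{n.name!r} ({n.time})"
                    )

    def postorder(self) -> Iterator[SpeciesNode]:
        return self.root.postorder()

    @property
    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def species_set(self) -> set:
        return {n.name for n in self.leaves}

    def __len__(self) -> int:
        return len(self.nodes)

    def newick(self, ranks: bool = False) -> str:
        """Newick string; with ``ranks`` internal labels are the time ranks,
        so the output round-trips through ``parse_species_tree(_, "labels")``.
        """
        def fmt(n: SpeciesNode) -> str:
            if n.is_leaf:
                return n.name
            label = str(n.time) if ranks else n.name
            return "(" + ",".join(fmt(c) for c in n.children) + ")" + label

        return fmt(self.root) + ";"

    def child_branches(self, name: str) -> tuple:
        """Names of the two child branches below internal node ``name``."""
        n = self.nodes[name]
        return tuple(c.name for c in n.children)


class SubdividedTree:
    """The dated subdivision S' of a species tree.

    Artificial (single-child) nodes are inserted on each branch at every
    internal time it crosses, named ``<branchChild>@<time>``.  ``slices[t]``
    holds the nodes of time t, sorted by name for determinism.
    """

    def __init__(self, root: SpeciesNode, species_tree: DatedSpeciesTree):
        self.root = root
        self.species_tree = species_tree
        self.nodes = {n.name: n for n in root.postorder()}
        self.slices: dict = {}
        for n in self.root.postorder():
            self.slices.setdefault(n.time, []).append(n)
        for t in self.slices:
            self.slices[t].sort(key=lambda n: n.name)
        self.times = sorted(self.slices)

    def postorder(self) -> Iterator[SpeciesNode]:
        return self.root.postorder()

    def co_timed(self, x: SpeciesNode) -> list:
        """Nodes sharing x's time slice, excluding x itself."""
        return [z for z in self.slices[x.time] if z is not x]

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# parsing


def _read_dendropy(newick_text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"could not parse Newick: {exc}") from exc


DatingSpec = Union[str, Mapping[str, int]]


def parse_species_tree(newick_text: str, dating: DatingSpec = "labels") -> DatedSpeciesTree:
    """Parse a rooted binary Newick species tree and date it.

    dating:
        * ``"labels"`` — internal-node labels are integer time ranks;
        * ``"heights"`` — ranks derived from node heights (max root-to-leaf
          branch-length distance below each node), ties broken by post-order
          index;
        * a mapping ``{internal node label: rank}``.
    """
    dtree = _read_dendropy(newick_text)

    def convert(dnode) -> SpeciesNode:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("species leaf without a label")
            node = SpeciesNode(dnode.taxon.label)
            node.species = node.name
            return node
        node = SpeciesNode(dnode.label if dnode.label else "")
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    _name_unlabeled(root, prefix="n")
    internals = [n for n in root.postorder() if not n.is_leaf]

    if isinstance(dating, Mapping):
        for n in root.postorder():
            if n.name in dating:
                if n.is_leaf:
                    raise TreeError(f"leaf {n.name!r} given a nonzero time rank")
                n.time = int(dating[n.name])
        missing = [n.name for n in internals if n.time == 0]
        if missing:
            raise TreeError(f"no time rank for internal nodes {missing}")
    elif dating == "labels":
        for n in internals:
            try:
                n.time = int(n.name)
            except ValueError:
                raise TreeError(
                    f"internal label {n.name!r} is not an integer rank "
                    "(dating='labels')"
                ) from None
        # ranks double as names; make names unique and readable
        if len({n.time for n in internals}) != len(internals):
            raise TreeError("duplicate internal time ranks")
        for n in internals:
            n.name = f"t{n.time}"
    elif dating == "heights":
        # node height = max branch-length distance to a descendant leaf
        heights: dict = {}
        post = list(root.postorder())
        dlens = _edge_lengths(dtree, root)
        for n in post:
            if n.is_leaf:
                heights[id(n)] = 0.0
            else:
                heights[id(n)] = max(
                    heights[id(c)] + dlens.get((n.name, c.name), 1.0)
                    for c in n.children
                )
        order = sorted(
            range(len(internals)), key=lambda i: (heights[id(internals[i])], i)
        )
        for rank, idx in enumerate(order, start=1):
            internals[idx].time = rank
    else:
        raise TreeError(f"unknown dating spec {dating!r}")

    tree = DatedSpeciesTree(root)
    return tree


def _name_unlabeled(root: _Node, prefix: str) -> None:
    """Give unlabeled internal nodes pre-order names <prefix>1, <prefix>2, ...
    skipping any name already present in the tree."""
    used = {n.name for n in root.postorder() if n.name}
    k = 0

    def walk(n: _Node) -> None:
        nonlocal k
        if not n.is_leaf:
            if not n.name:
                k += 1
                while f"{prefix}{k}" in used:
                    k += 1
                n.name = f"{prefix}{k}"
                used.add(n.name)
            for c in n.children:
                walk(c)

    walk(root)


def _edge_lengths(dtree: dendropy.Tree, root: SpeciesNode) -> dict:
    """Branch lengths keyed on (parent name, child name), best effort."""
    out = {}

    def walk(dnode, node):
        for dc, c in zip(dnode.child_nodes(), node.children):
            if dc.edge.length is not None:
                out[(node.name, c.name)] = float(dc.edge.length)
            walk(dc, c)

    walk(dtree.seed_node, root)
    return out


def read_leaf_map(source: Union[str, io.TextIOBase]) -> dict:
    """Read a two-column TSV mapping gene leaf -> species label."""
    if isinstance(source, str):
        fh: io.TextIOBase = open(source)
        close = True
    else:
        fh, close = source, False
    mapping = {}
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise TreeError(f"malformed leaf-map line: {line!r}")
            mapping[parts[0]] = parts[1]
    finally:
        if close:
            fh.close()
    return mapping


def parse_gene_tree(
    newick_text: str,
    species_labels: Optional[set] = None,
    sep: Optional[str] = "_",
    leaf_map: Optional[Mapping[str, str]] = None,
) -> GeneTree:
    """Parse a rooted binary Newick gene tree and resolve leaf species.

    A leaf's species is taken from ``leaf_map`` when given, else from the
    label's last ``sep``-separated field (``a_A`` -> species ``A``).  When
    ``species_labels`` is provided, every resolved species must belong to it.
    """
    dtree = _read_dendropy(newick_text)

    def convert(dnode) -> GeneNode:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("gene leaf without a label")
            label = dnode.taxon.label
            if leaf_map and label in leaf_map:
                sp = leaf_map[label]
            elif sep and sep in label:
                sp = label.rsplit(sep, 1)[1]
            else:
                raise TreeError(f"cannot resolve species of gene leaf {label!r}")
            return GeneNode(label, species=sp)
        node = GeneNode(dnode.label if dnode.label else "")
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    _name_unlabeled(root, prefix="g")
    tree = GeneTree(root)
    if species_labels is not None:
        extra = tree.species_set - set(species_labels)
        if extra:
            raise TreeError(
                f"gene leaves mapped to species absent from the species tree: "
                f"{sorted(extra)}"
            )
    return tree


# ---------------------------------------------------------------------------
# subdivision


def subdivide(species_tree: DatedSpeciesTree) -> SubdividedTree:
    """Build the dated subdivision S' of a species tree.

    On each branch (p, u), one artificial node is inserted at every internal
    time z with time(u) < z < time(p).
    """

    def build(snode: SpeciesNode) -> SpeciesNode:
        node = SpeciesNode(snode.name, snode.time)
        node.kind = "leaf" if snode.is_leaf else "speciation"
        node.s_branch = snode.name
        node.species = snode.name if snode.is_leaf else None
        for child in snode.children:
            sub = build(child)
            top = sub
            # chain of artificial nodes from just below time(snode) down to child
            for t in range(child.time + 1, snode.time):
                art = SpeciesNode(f"{child.name}@{t}", t)
                art.kind = "artificial"
                art.s_branch = child.name
                art.add_child(top)
                top = art
            node.add_child(top)
        return node

    return SubdividedTree(build(species_tree.root), species_tree)
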