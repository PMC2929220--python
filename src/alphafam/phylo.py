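"""Distance-based phylogenetics: neighbor joining, rooting, path queries.

Trees are held as :class:`dendropy.Tree` objects wrapped in
:class:`PhyloTree`, which adds the leaf-label conveniences the pipeline
needs (path lengths, outgroup rooting, Newick round-trips).  The NJ
implementation is the classical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion; pair-selection ties break lexicographically
on the smallest leaf label under each candidate node, so runs are
deterministic.  Negative branch lengths produced by NJ are kept by
default and can be clamped to zero on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .evodist import DistanceMatrix


@dataclass
class PhyloTree:
    """A leaf-labeled tree with branch lengths."""

    tree: dendropy.Tree
    rooted: bool = False

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def _leaf(self, label: str) -> dendropy.Node:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"no leaf labeled {label!r}")

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                real_value_format_specifier=".10g",
            ).strip()
        )

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True,
        )
        return cls(tree=tree, rooted=rooted)

    def clone(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick(), rooted=self.rooted)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.edges() if e.head_node.parent_node
        )


def read_newick(path, rooted: bool = False) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), rooted=rooted)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou–Nei neighbor joining on a distance matrix (unrooted tree).

    With an additive input matrix the returned tree's path metric
    reproduces the matrix exactly (up to float round-off).
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[str, dendropy.Node] = {}
    lengths: dict[str, float] = {}  # pendant edge length, set at join time
    for label in D.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes[label] = node
    # Active cluster keys: the lexicographically smallest leaf label below
    # each node, used for deterministic tie-breaking.
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((D.labels[i], D.labels[j]))] = float(D.values[i, j])
    active = sorted(nodes)

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (r - 2) * d(a, b) - row_sum[a] - row_sum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d(a, b)
        la = dab / 2.0 + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new_key = min(a, b)
        new_dist = {}
        for c in active:
            if c in (a, b):
                continue
            new_dist[c] = (d(a, c) + d(b, c) - dab) / 2.0
        active = sorted(set(active) - {a, b} | {new_key})
        nodes[new_key] = parent
        for c, v in new_dist.items():
            dist[frozenset((new_key, c))] = v

    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = d(a, b) - la
    lc = d(a, c) - la
    seed = tree.seed_node
    for key, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[key])
        nodes[key].edge.length = length

    if clamp_negative:
        for edge in tree.edges():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
    tree.is_rooted = False
    return PhyloTree(tree=tree, rooted=False)


def root_at(tree: PhyloTree, outgroup_leaf: str) -> PhyloTree:
    """Root a tree on the outgroup's pendant edge (at its midpoint).

    Leaf-to-leaf path lengths are preserved exactly; the input tree is not
    modified.
    """
    out = tree.clone()
    leaf = out._leaf(outgroup_leaf)
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    out.tree.reroot_at_edge(edge, length1=half, length2=half,
                            update_bipartitions=False)
    out.tree.is_rooted = True
    out.rooted = True
    # Collapse any degree-2 node left behind by rerooting an unrooted tree.
    out.tree.suppress_unifurcations()
    return out


def path_length(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if a == b:
        tree._leaf(a)
        return 0.0
    na, nb = tree._leaf(a), tree._leaf(b)
    depth_a: dict[int, float] = {}
    node, acc = na, 0.0
    while node is not None:
        depth_a[id(node)] = acc
        if node.parent_node is not None:
            acc += node.edge.length or 0.0
        node = node.parent_node
    node, acc = nb, 0.0
    while id(node) not in depth_a:
        acc += node.edge.length or 0.0
        node = node.parent_node
    return acc + depth_a[id(node)]


@dataclass(frozen=True)
class SubfamilyAssignment:
    """Mapping of leaf id to subfamily label ('unassigned' where ambiguous)."""

    labels: dict[str, str]

    def __getitem__(self, leaf: str) -> str:
        return self.labels[leaf]


def classify_subfamilies(
    tree: PhyloTree, references: dict[str, str]
) -> SubfamilyAssignment:
    """Assign each leaf the subfamily of the nearest enclosing reference clade.

    ``references`` maps reference leaf labels (e.g. the fly subfamily
    representatives) to subfamily names.  For every other leaf, ancestors
    are walked rootward; the first clade (below the root) containing at
    least one reference decides: a single reference label assigns it,
    conflicting labels yield ``unassigned``.
    """
    if not tree.rooted:
        raise ValueError("subfamily classification requires a rooted tree")
    present = set(tree.leaf_labels)
    missing = set(references) - present
    if missing:
        raise KeyError(f"reference leaves missing from tree: {sorted(missing)}")
    out: dict[str, str] = {}
    root = tree.tree.seed_node
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in references:
            out[label] = references[label]
            continue
        assigned = "unassigned"
        node = leaf.parent_node
        while node is not None and node is not root:
            clade_refs = {
                references[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in references
            }
            if clade_refs:
                assigned = clade_refs.pop() if len(clade_refs) == 1 else "unassigned"
                break
            node = node.parent_node
        out[label] = assigned
    return SubfamilyAssignment(labels=out)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson–Foulds (symmetric bipartition) distance."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.to_newick(), schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.to_newick(), schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
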