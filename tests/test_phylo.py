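"""Neighbor joining, rooting, path queries, subfamily classification."""

import numpy as np
import pytest

from alphafam.evodist import DistanceMatrix
from alphafam.phylo import (
    PhyloTree,
    classify_subfamilies,
    neighbor_joining,
    path_length,
    robinson_foulds,
    root_at,
)
from alphafam.simfam import random_tree, tree_distance_matrix


class TestNeighborJoining:
    def test_three_taxa_pendant_lengths(self):
        D = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        tree = neighbor_joining(D)
        assert path_length(tree, "A", "B") == pytest.approx(2.0)
        assert path_length(tree, "A", "C") == pytest.approx(4.0)
        assert path_length(tree, "B", "C") == pytest.approx(4.0)
        # three-point formulas give pendants 1, 1, 3
        newick = tree.to_newick()
        assert "A:1" in newick and "B:1" in newick and "C:3" in newick

    def test_too_few_taxa(self):
        D = DistanceMatrix(labels=["A", "B"], values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            neighbor_joining(D)

    @pytest.mark.parametrize("n_leaves", [4, 5, 8, 12])
    def test_inverts_additive_matrices(self, n_leaves, rng):
        for _ in range(10):
            true = random_tree(n_leaves, rng)
            D = tree_distance_matrix(true)
            inferred = neighbor_joining(D)
            assert robinson_foulds(true, inferred) == 0
            D2 = tree_distance_matrix(inferred)
            assert np.allclose(D.values, D2.values, atol=1e-9)

    def test_deterministic_on_ties(self):
        # fully symmetric distances: result decided by the lexicographic rule
        values = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(labels=["a", "b", "c", "d"], values=values)
        t1 = neighbor_joining(D).to_newick()
        t2 = neighbor_joining(D).to_newick()
        assert t1 == t2

    def test_clamp_negative_lengths(self):
        # A non-additive matrix that produces a negative NJ branch.
        values = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.05],
                [0.4, 0.4, 0.05, 0.0],
            ]
        )
        D = DistanceMatrix(labels=["a", "b", "c", "d"], values=values)
        clamped = neighbor_joining(D, clamp_negative=True)
        lengths = [
            e.length
            for e in clamped.tree.edges()
            if e.length is not None
        ]
        assert all(l >= 0 for l in lengths)


class TestRooting:
    def test_three_leaf_outgroup_rooting(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:3);")
        rooted = root_at(tree, "C")
        assert rooted.rooted
        root = rooted.tree.seed_node
        assert len(root.child_nodes()) == 2
        # outgroup pendant edge split at its midpoint
        leaf_c = rooted._leaf("C")
        assert leaf_c.edge.length == pytest.approx(1.5)
        assert path_length(rooted, "A", "C") == pytest.approx(4.0)

    def test_leaf_paths_invariant_under_rooting(self, rng):
        for _ in range(10):
            tree = random_tree(7, rng)
            labels = tree.leaf_labels
            outgroup = labels[0]
            rooted = root_at(tree, outgroup)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    assert path_length(rooted, a, b) == pytest.approx(
                        path_length(tree, a, b), abs=1e-9
                    )

    def test_double_rooting_idempotent_on_paths(self, rng):
        tree = random_tree(6, rng)
        out = tree.leaf_labels[2]
        once = root_at(tree, out)
        twice = root_at(once, out)
        for a in tree.leaf_labels:
            for b in tree.leaf_labels:
                assert path_length(twice, a, b) == pytest.approx(
                    path_length(once, a, b), abs=1e-9
                )

    def test_total_length_invariant_under_rooting(self, rng):
        tree = random_tree(9, rng)
        rooted = root_at(tree, tree.leaf_labels[4])
        assert rooted.total_length() == pytest.approx(
            tree.total_length(), abs=1e-9
        )

    def test_unknown_leaf_is_error(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:3);")
        with pytest.raises(KeyError):
            root_at(tree, "Z")


class TestPathLength:
    def test_worked_example(self):
        tree = PhyloTree.from_newick("((A:1,B:2):3,C:4);", rooted=True)
        assert path_length(tree, "A", "C") == pytest.approx(8.0)
        assert path_length(tree, "A", "B") == pytest.approx(3.0)

    def test_self_path_is_zero(self):
        tree = PhyloTree.from_newick("((A:1,B:2):3,C:4);", rooted=True)
        assert path_length(tree, "A", "A") == 0.0

    def test_matches_graph_shortest_path(self, rng):
        # Oracle: all-pairs shortest paths on the tree as a weighted graph.
        import itertools

        tree = random_tree(8, rng)
        nodes = list(tree.tree.preorder_node_iter())
        index = {id(n): k for k, n in enumerate(nodes)}
        n = len(nodes)
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
        for node in nodes[1:]:
            i, j = index[id(node)], index[id(node.parent_node)]
            w = node.edge.length or 0.0
            dist[i, j] = dist[j, i] = w
        for k, i, j in itertools.product(range(n), repeat=3):
            if dist[i, k] + dist[k, j] < dist[i, j]:
                dist[i, j] = dist[i, k] + dist[k, j]
        leaves = {
            leaf.taxon.label: index[id(leaf)]
            for leaf in tree.tree.leaf_node_iter()
        }
        for a in leaves:
            for b in leaves:
                assert path_length(tree, a, b) == pytest.approx(
                    dist[leaves[a], leaves[b]], abs=1e-9
                )


class TestNewickRoundTrip:
    def test_topology_and_lengths_preserved(self, rng):
        tree = random_tree(10, rng)
        back = PhyloTree.from_newick(tree.to_newick())
        assert robinson_foulds(tree, back) == 0
        for a in tree.leaf_labels:
            for b in tree.leaf_labels:
                assert path_length(back, a, b) == pytest.approx(
                    path_length(tree, a, b), abs=1e-9
                )


class TestClassifySubfamilies:
    REFS = {"ref1": "a1", "ref2": "a2", "ref3": "a3"}

    def test_toy_tree_clade_labels(self):
        newick = (
            "(out:2,((ref1:0.2,x1:0.2):0.5,"
            "((ref2:0.2,x2:0.2):0.4,(ref3:0.2,x3:0.2):0.4):0.2):0.5);"
        )
        tree = root_at(PhyloTree.from_newick(newick), "out")
        asg = classify_subfamilies(tree, self.REFS)
        assert asg["x1"] == "a1"
        assert asg["x2"] == "a2"
        assert asg["x3"] == "a3"
        assert asg["ref1"] == "a1"
        assert asg["out"] == "unassigned"

    def test_leaf_between_two_references_is_unassigned(self):
        newick = "(out:2,(y:0.5,(ref1:0.3,ref2:0.3):0.3):0.5);"
        tree = root_at(PhyloTree.from_newick(newick), "out")
        asg = classify_subfamilies(tree, {"ref1": "a1", "ref2": "a2"})
        assert asg["y"] == "unassigned"

    def test_missing_reference_is_error(self):
        tree = root_at(PhyloTree.from_newick("(out:1,(a:1,b:1):1);"), "out")
        with pytest.raises(KeyError):
            classify_subfamilies(tree, {"nope": "a1"})

    def test_requires_rooted_tree(self):
        tree = PhyloTree.from_newick("(a:1,b:1,ref1:1);")
        with pytest.raises(ValueError):
            classify_subfamilies(tree, {"ref1": "a1"})
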