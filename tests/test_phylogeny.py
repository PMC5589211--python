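"""UPGMA, Fitch scoring, parsimony ratchet, ACCTRAN branch lengths."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from neoscape import phylogeny as ph


def branch_sum(tree: ph.Tree) -> float:
    total = 0.0

    def walk(n):
        nonlocal total
        total += n.length
        for c in n.children:
            walk(c)

    walk(tree.root)
    return total - tree.root.length


def brute_force_min_changes(tree: ph.Tree, matrix: pd.DataFrame) -> int:
    """Oracle: minimize changes over every assignment of 0/1 states to the
    internal nodes, independently per character."""
    internals = []

    def collect(n):
        if not n.is_leaf:
            internals.append(n)
        for c in n.children:
            collect(c)

    collect(tree.root)
    leaf_state = {t: matrix.loc[t].to_numpy() for t in matrix.index}
    total = 0
    for j in range(matrix.shape[1]):
        best = np.inf
        for assign in itertools.product((0, 1), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}

            def node_state(n):
                return (
                    leaf_state[n.name][j] if n.is_leaf else state[id(n)]
                )

            changes = 0

            def walk(n):
                nonlocal changes
                for c in n.children:
                    changes += node_state(c) != node_state(n)
                    walk(c)

            walk(tree.root)
            best = min(best, changes)
        total += best
    return int(total)


def to_dendropy(newick: str, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    t.encode_bipartitions()
    return t


class TestUpgma:
    def test_hand_three_taxon_example(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = ph.upgma(d)
        # A and B join first at height 1
        inner = next(c for c in tree.root.children if not c.is_leaf)
        assert sorted(l.name for l in inner.children) == ["A", "B"]
        assert inner.children[0].length == pytest.approx(1.0)
        outer = next(c for c in tree.root.children if c.is_leaf)
        assert outer.name == "C" and outer.length == pytest.approx(3.0)

    def test_identical_rows_zero_height_join(self):
        m = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=list("ABC"),
            columns=["c1", "c2", "c3"],
        )
        tree = ph.upgma(ph.hamming_distances(m))
        inner = next(c for c in tree.root.children if not c.is_leaf)
        assert all(l.length == 0 for l in inner.children)

    def test_two_taxa_split_edge(self):
        d = pd.DataFrame([[0, 4], [4, 0]], index=list("AB"), columns=list("AB"),
                         dtype=float)
        tree = ph.upgma(d)
        assert [c.length for c in tree.root.children] == [2.0, 2.0]

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"),
                         dtype=float)
        with pytest.raises(ph.PhylogenyError):
            ph.upgma(d)


class TestFitchScore:
    def test_three_taxon_two_characters(self):
        m = pd.DataFrame({"c1": [1, 1, 0], "c2": [0, 1, 0]}, index=list("ABC"))
        tree = ph.upgma(ph.hamming_distances(m))
        assert ph.fitch_score(tree, m) == 2

    def test_identical_rows_zero_score(self):
        m = pd.DataFrame({"c1": [1, 1, 1], "c2": [0, 0, 0]}, index=list("ABC"))
        tree = ph.upgma(pd.DataFrame(np.zeros((3, 3)), index=list("ABC"),
                                     columns=list("ABC")))
        assert ph.fitch_score(tree, m) == 0

    def test_truncal_character_costs_one_with_outgroup(self):
        m = pd.DataFrame({"c1": [1, 1, 1, 0]}, index=["A", "B", "C", "normal"])
        for tree in ph.enumerate_unrooted_topologies(["A", "B", "C", "normal"]):
            assert ph.fitch_score(tree, m) == 1

    def test_matches_brute_force_assignment_oracle(self, rng):
        for trial in range(10):
            n_taxa = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n_taxa)]
            m = pd.DataFrame(
                rng.integers(0, 2, size=(n_taxa, 12)), index=taxa,
                columns=[f"c{j}" for j in range(12)],
            )
            tree = ph.upgma(ph.hamming_distances(m))
            assert ph.fitch_score(tree, m) == brute_force_min_changes(tree, m)

    def test_invariant_under_rerooting(self, rng):
        taxa = list("ABCDEF")
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 25)), index=taxa,
                         columns=[f"c{j}" for j in range(25)])
        tree = ph.upgma(ph.hamming_distances(m))
        ref = ph.fitch_score(tree, m)
        for leaf in taxa:
            assert ph.fitch_score(ph.reroot_at_leaf(tree, leaf), m) == ref

    def test_missing_taxon_rejected(self):
        m = pd.DataFrame({"c1": [1, 0]}, index=["A", "B"])
        tree = ph.Tree(root=ph.Node(children=[ph.Node(name="A"),
                                              ph.Node(name="X")]))
        with pytest.raises(ph.PhylogenyError):
            ph.fitch_score(tree, m)


class TestRatchet:
    def test_three_taxa_returns_start_unchanged(self):
        m = pd.DataFrame({"c1": [1, 1, 0]}, index=list("ABC"))
        start = ph.upgma(ph.hamming_distances(m))
        out = ph.parsimony_ratchet(m, start=start, iterations=5, seed=0)
        assert sorted(out.taxa()) == sorted(start.taxa())
        assert out.parsimony_score == 1

    def test_seed_determinism(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 30)), index=list("ABCDEF"),
                         columns=[f"c{j}" for j in range(30)])
        t1 = ph.parsimony_ratchet(m, iterations=30, seed=11)
        t2 = ph.parsimony_ratchet(m, iterations=30, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_never_worse_than_start(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(7, 40)), index=list("ABCDEFG"),
                         columns=[f"c{j}" for j in range(40)])
        start = ph.upgma(ph.hamming_distances(m))
        out = ph.parsimony_ratchet(m, start=start, iterations=20, seed=3)
        assert out.parsimony_score <= ph.fitch_score(start, m)

    def test_recovers_generating_topology_from_clean_characters(self):
        """40 noiseless clade characters simulated on a known 6-taxon tree:
        the search must recover that topology (RF distance 0)."""
        clades = [("A", "B"), ("C", "D"), ("E", "F"), ("A", "B", "C", "D")]
        cols = {}
        k = 0
        for clade in clades:
            for _ in range(10):
                cols[f"c{k}"] = [1 if t in clade else 0 for t in "ABCDEF"]
                k += 1
        m = pd.DataFrame(cols, index=list("ABCDEF"))
        tree = ph.parsimony_ratchet(m, iterations=30, seed=4)
        assert tree.parsimony_score == 40
        tns = dendropy.TaxonNamespace()
        found = to_dendropy(tree.to_newick(), tns)
        truth = to_dendropy("((A,B),((C,D),(E,F)));", tns)
        assert dendropy.calculate.treecompare.symmetric_difference(found, truth) == 0

    def test_finds_exhaustive_minimum_on_random_matrices(self, rng):
        hits = 0
        runs = 8  # scaled-down here; the 20-run suite is in acceptance
        for i in range(runs):
            m = pd.DataFrame(rng.integers(0, 2, size=(6, 30)),
                             index=list("ABCDEF"),
                             columns=[f"c{j}" for j in range(30)])
            m = m.loc[:, m.sum(axis=0) > 0]
            tree = ph.parsimony_ratchet(m, iterations=100, seed=100 + i)
            hits += tree.parsimony_score == ph.exhaustive_min_score(m)
        assert hits == runs

    def test_bad_iterations_rejected(self):
        m = pd.DataFrame({"c1": [1, 0, 1, 0]}, index=list("ABCD"))
        with pytest.raises(ph.PhylogenyError):
            ph.parsimony_ratchet(m, iterations=0, seed=1)


class TestAcctran:
    def test_branch_sum_equals_parsimony_score(self, rng):
        for i in range(5):
            m = pd.DataFrame(rng.integers(0, 2, size=(6, 20)),
                             index=list("ABCDEF"),
                             columns=[f"c{j}" for j in range(20)])
            tree = ph.parsimony_ratchet(m, iterations=10, seed=i)
            assert branch_sum(tree) == tree.parsimony_score

    def test_three_taxon_total_length(self):
        m = pd.DataFrame({"c1": [1, 1, 0], "c2": [0, 1, 0]}, index=list("ABC"))
        tree = ph.acctran_branch_lengths(ph.upgma(ph.hamming_distances(m)), m)
        assert branch_sum(tree) == 2 == tree.parsimony_score

    def test_truncal_characters_map_to_outgroup_adjacent_edge(self):
        # 5 truncal characters: single origin on the ingroup root edge
        m = pd.DataFrame(
            {f"c{j}": [1, 1, 1, 0] for j in range(5)},
            index=["A", "B", "C", "normal"],
        )
        tree = ph.reroot_at_leaf(ph.upgma(ph.hamming_distances(m)), "normal")
        tree = ph.acctran_branch_lengths(tree, m)
        ingroup = next(c for c in tree.root.children if not c.is_leaf)
        assert ingroup.length == 5.0
        assert branch_sum(tree) == 5

    def test_zero_change_character_adds_nothing(self):
        m = pd.DataFrame({"c1": [1, 1, 1], "c2": [1, 1, 0]}, index=list("ABC"))
        tree = ph.acctran_branch_lengths(ph.upgma(ph.hamming_distances(m)), m)
        assert branch_sum(tree) == 1


class TestNewickExport:
    def test_newick_is_parseable_and_preserves_taxa(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 15)), index=list("ABCDE"),
                         columns=[f"c{j}" for j in range(15)])
        tree = ph.parsimony_ratchet(m, iterations=10, seed=2)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == list("ABCDE")
        total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert total == tree.parsimony_score
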