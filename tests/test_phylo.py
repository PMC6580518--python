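"""Poisson distances, neighbor joining, bootstrap and subclass labeling."""

import numpy as np
import pytest

from hsfkit import phylo
from hsfkit.phylo import (
    MultipleAlignment,
    PhyloTree,
    SaturatedDistance,
    align_star,
    bootstrap_support,
    distance_matrix,
    label_subclasses,
    nj_tree,
    poisson_distance,
)
from hsfkit.seqcore import ProteinRecord


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        assert poisson_distance("ACDEF", "ACDEF") == 0.0

    def test_analytic_inverse(self):
        # p = 1 - e^-1 gives d = 1 exactly
        n = 1000000
        k = round((1 - np.exp(-1)) * n)
        row_a = "A" * n
        row_b = "C" * k + "A" * (n - k)
        assert poisson_distance(row_a, row_b) == pytest.approx(1.0, abs=1e-5)

    def test_pairwise_deletion_drops_gap_columns(self):
        # gap column removed: 3 retained sites, 1 mismatch
        d = poisson_distance("AC-G", "ACTG")
        assert d == 0.0
        d2 = poisson_distance("AC-G", "ACTT")
        assert d2 == pytest.approx(-np.log(1 - 1 / 3))

    def test_saturation_and_empty_errors(self):
        with pytest.raises(SaturatedDistance):
            poisson_distance("AAAA", "CCCC")
        with pytest.raises(SaturatedDistance):
            poisson_distance("--", "AA")

    def test_monotone_in_mismatch_proportion(self):
        base = "A" * 100
        prev = -1.0
        for k in range(0, 90, 10):
            other = "C" * k + "A" * (100 - k)
            d = poisson_distance(base, other)
            assert d > prev
            prev = d


def _random_additive_tree(n_leaves: int, rng):
    """Random binary tree with uniform branch lengths; returns (distance
    matrix, leaf names, bipartitions)."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = f"N{nxt}"
        nxt += 1
        g.add_edge(nodes[i], new, length=float(rng.uniform(0.1, 1.0)))
        g.add_edge(nodes[j], new, length=float(rng.uniform(0.1, 1.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    g.add_edge(nodes[0], nodes[1], length=float(rng.uniform(0.1, 1.0)))
    tree = PhyloTree(g, leaves)
    return tree.distance_matrix(), leaves, tree.bipartitions()


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        # additive distances from ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(D, ids)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        np.testing.assert_allclose(tree.distance_matrix(ids), D, atol=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        d = tree.patristic("a")
        # closed form: branch to a = (d_ab + d_ac - d_bc) / 2
        inner = [n for n in tree.graph.nodes if n.startswith("_nj")][0]
        assert tree.graph.edges["a", inner]["length"] == pytest.approx(0.5)
        assert d["b"] == pytest.approx(2) and d["c"] == pytest.approx(3)

    def test_two_taxa_degenerate(self):
        tree = nj_tree(np.array([[0.0, 1.5], [1.5, 0.0]]), ["x", "y"])
        assert tree.patristic("x")["y"] == pytest.approx(1.5)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        D, ids, splits = _random_additive_tree(6, rng)
        perm = rng.permutation(len(ids))
        D2 = D[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assert nj_tree(D2, ids2).bipartitions() == nj_tree(D, ids).bipartitions()

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(4, 7))
            D, ids, splits = _random_additive_tree(n, rng)
            tree = nj_tree(D, ids)
            assert tree.bipartitions() == splits
            np.testing.assert_allclose(tree.distance_matrix(ids), D, atol=1e-9)

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        D, ids, splits = _random_additive_tree(6, rng)
        D = (D + D.T) / 2.0  # remove float asymmetry from path sums
        sk_tree = skbio_nj(DistanceMatrix(D, ids))
        sk_splits = set()
        for node in sk_tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if min(ids) in tips:
                tips = frozenset(set(ids) - tips)
            if 1 < len(tips) < len(ids) - 1:
                sk_splits.add(tips)
        assert nj_tree(D, ids).bipartitions() == sk_splits


class TestBootstrap:
    def _signal_alignment(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        def jitter(s, k, seed):
            r = np.random.default_rng(seed)
            s = list(s)
            for i in r.choice(len(s), size=k, replace=False):
                s[i] = "W" if s[i] != "W" else "Y"
            return "".join(s)
        rows = [jitter(base, 3, i) for i in range(4)] + \
               [jitter(other, 3, 10 + i) for i in range(4)]
        return MultipleAlignment([f"t{i}" for i in range(8)], rows)

    def test_strong_split_gets_full_support(self):
        aln = self._signal_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        key = frozenset({"t4", "t5", "t6", "t7"})
        assert tree.supports[key] == 100.0

    def test_zero_replicates_leaves_tree_unchanged(self):
        aln = self._signal_alignment()
        tree = bootstrap_support(aln, n_reps=0, seed=3)
        assert tree.supports == {}

    def test_seed_reproducibility(self):
        aln = self._signal_alignment()
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert t1.supports == t2.supports

    def test_newick_contains_supports(self):
        aln = self._signal_alignment()
        tree = bootstrap_support(aln, n_reps=20, seed=1)
        nwk = tree.newick()
        assert nwk.endswith(";") and ")100" in nwk


class TestSubclassLabeling:
    def test_sister_reference_label(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edge("q", "n1", length=0.1)
        g.add_edge("ref", "n1", length=0.1)
        g.add_edge("n1", "n2", length=1.0)
        g.add_edge("far", "n2", length=0.1)
        tree = PhyloTree(g, ["q", "ref", "far"])
        out = label_subclasses(tree, {"ref": "A4a", "far": "B1"})
        assert out["q"] == "A4a"

    def test_tie_broken_lexicographically(self):
        import networkx as nx
        g = nx.Graph()
        for leaf in ("q", "r1", "r2"):
            g.add_edge(leaf, "hub", length=0.5)
        tree = PhyloTree(g, ["q", "r1", "r2"])
        out = label_subclasses(tree, {"r1": "A1a", "r2": "A1a"})
        assert out["q"] == "A1a"

    def test_no_references_raises(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edge("a", "b", length=1.0)
        with pytest.raises(ValueError):
            label_subclasses(PhyloTree(g, ["a", "b"]), {"zz": "A1a"})

    def test_full_manifest_recovery(self, full_dataset, full_summary):
        truth = full_dataset.manifest["genes"]
        calls = full_summary["subclass_calls"]
        assert all(calls[g] == truth[g]["subclass"] for g in truth)


class TestCenterStar:
    def test_rows_degap_to_inputs(self):
        recs = [
            ProteinRecord("a", "MKVLDEWF"),
            ProteinRecord("b", "MKVDEWF"),
            ProteinRecord("c", "MKVLDWF"),
        ]
        aln = align_star(recs)
        for rec, row in zip(recs, aln.rows):
            assert row.replace("-", "") == rec.sequence

    def test_identical_sequences_align_without_gaps(self):
        recs = [ProteinRecord(i, "MKVLDEWFAY") for i in ("a", "b", "c")]
        aln = align_star(recs)
        assert all(row == "MKVLDEWFAY" for row in aln.rows)

    def test_distance_matrix_symmetry(self):
        aln = MultipleAlignment(["a", "b", "c"],
                                ["ACDEF", "ACDFF", "AC-EF"])
        D = distance_matrix(aln)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
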