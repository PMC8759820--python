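"""Distances, neighbor joining, SNP counting, tree comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainkit import (
    Assembly,
    DistanceMatrix,
    distance_concordance,
    nj_tree,
    robinson_foulds,
    snp_distance,
    te_distance,
    tree_distance_matrix,
)
from strainkit.conservation import PairConservation
from strainkit.simulate import mutate_sequence, random_sequence, random_te_library
from strainkit.trees import Tree, TreeNode


def _pc(a, b, n_a, n_b, n_shared):
    return PairConservation(
        a, b, [(i, i, 1.0, 1.0) for i in range(n_shared)], n_a, n_b
    )


def _random_tree(labels, rng, min_len=0.05, max_len=1.0):
    """Random rooted binary tree with branch lengths in [min_len, max_len]."""
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        nodes.append(TreeNode(children=[a, b]))
    return Tree(nodes[0])


class TestNewick:
    def test_round_trip(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.06);"
        t = Tree.from_newick(nwk)
        t2 = Tree.from_newick(t.to_newick())
        assert t.bipartitions() == t2.bipartitions()
        assert sorted(t.leaf_names()) == ["A", "B", "C", "D"]

    @pytest.mark.parametrize("bad", ["(A,B", "(A,B);x", "A:0.1"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            Tree.from_newick(bad)


class TestTeDistance:
    def test_identical_sets_give_zero(self):
        pairs = {
            ("A", "B"): _pc("A", "B", 4, 4, 4),
            ("A", "C"): _pc("A", "C", 4, 4, 4),
            ("B", "C"): _pc("B", "C", 4, 4, 4),
        }
        d = te_distance(pairs)
        assert np.allclose(d.values, 0)

    def test_disjoint_sets_give_one(self):
        pairs = {("A", "B"): _pc("A", "B", 3, 5, 0),
                 ("A", "C"): _pc("A", "C", 3, 3, 0),
                 ("B", "C"): _pc("B", "C", 5, 3, 0)}
        assert te_distance(pairs)[("A", "B")] == 1.0

    def test_union_normalized_value(self):
        pairs = {("A", "B"): _pc("A", "B", 4, 4, 2),
                 ("A", "C"): _pc("A", "C", 4, 4, 4),
                 ("B", "C"): _pc("B", "C", 4, 4, 4)}
        assert te_distance(pairs)[("A", "B")] == pytest.approx(4 / 6)
        assert te_distance(pairs, method="average")[("A", "B")] == pytest.approx(0.5)

    def test_missing_pair_reported(self):
        pairs = {("A", "B"): _pc("A", "B", 4, 4, 2),
                 ("A", "C"): _pc("A", "C", 4, 4, 4)}
        with pytest.raises(ValueError, match=r"\('B', 'C'\)"):
            te_distance(pairs)

    def test_empty_pair_undefined(self):
        pairs = {("A", "B"): _pc("A", "B", 0, 0, 0),
                 ("A", "C"): _pc("A", "C", 1, 1, 1),
                 ("B", "C"): _pc("B", "C", 1, 1, 1)}
        with pytest.raises(ValueError, match="undefined"):
            te_distance(pairs)


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, -1], [-1, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[1.0, 1], [1, 0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 0.6, 0.8, 0.4
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, 0.4, 0]]),
        )
        t = nj_tree(d)
        lengths = {n.name: n.length for n in t.root.walk() if n.is_leaf}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self, rng):
        true = _random_tree(["A", "B", "C", "D"], rng)
        d = tree_distance_matrix(true)
        inferred = nj_tree(d)
        assert robinson_foulds(inferred, true) == 0
        np.testing.assert_allclose(
            tree_distance_matrix(inferred).values, d.values, atol=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(4, 8), seed=st.integers(0, 10_000))
    def test_nj_exact_on_additive_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = [f"L{i}" for i in range(n)]
        true = _random_tree(labels, rng)
        d = tree_distance_matrix(true)
        inferred = nj_tree(d)
        assert robinson_foulds(inferred, true) == 0
        np.testing.assert_allclose(
            tree_distance_matrix(inferred).values, d.values, atol=1e-9
        )

    def test_topology_invariant_to_label_order(self, rng):
        true = _random_tree(["A", "B", "C", "D", "E"], rng)
        d = tree_distance_matrix(true)
        perm = [3, 1, 4, 0, 2]
        d2 = DistanceMatrix(
            [d.labels[i] for i in perm], d.values[np.ix_(perm, perm)]
        )
        assert robinson_foulds(nj_tree(d), nj_tree(d2)) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 1], [1, 0]])))


class TestRobinsonFoulds:
    def test_self_distance_zero(self, rng):
        t = _random_tree(list("ABCDEF"), rng)
        assert robinson_foulds(t, t) == 0

    def test_distinct_quartet_topologies_differ_by_two(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = Tree.from_newick("((A:1,B:1):1,C:1);")
        t2 = Tree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(t1, t2)

    def test_agrees_with_dendropy_on_random_pairs(self):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(99)
        labels = [f"T{i}" for i in range(8)]
        for _ in range(50):
            t1 = _random_tree(labels, rng)
            t2 = _random_tree(labels, rng)
            ours = robinson_foulds(t1, t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.to_newick(), schema="newick", taxon_namespace=tns
            )
            d2 = dendropy.Tree.get(
                data=t2.to_newick(), schema="newick", taxon_namespace=tns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            theirs = treecompare.symmetric_difference(d1, d2)
            assert ours == theirs


class TestSnpDistance:
    def _asm(self, seq):
        a = Assembly()
        a.add("chr", seq)
        return a

    def test_identical_assemblies_give_zero(self, rng):
        seq = random_sequence(30_000, rng)
        assert snp_distance(self._asm(seq), self._asm(seq)) == 0

    @pytest.mark.parametrize("k", [1, 10, 137])
    def test_planted_substitutions_counted_exactly(self, rng, k):
        seq = random_sequence(30_000, rng)
        mutated = mutate_sequence(seq, k, seed=k)
        a, b = self._asm(seq), self._asm(mutated)
        assert snp_distance(a, b) == k
        assert snp_distance(b, a) == k

    def test_insertion_breaks_blocks_without_adding_mismatches(self, rng):
        """An insertion splits the anchor chain but adds no mismatches.
        Substitutions are planted away from the breakpoint: the anchor-free
        window around an indel is skipped by construction."""
        seq = random_sequence(30_000, rng)
        breakpoint_ = 15_000
        sites = [200 + 900 * i for i in range(25) if abs(200 + 900 * i - breakpoint_) > 60]
        k = len(sites)
        arr = list(seq)
        for s in sites:
            arr[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[s]]
        mutated = "".join(arr)
        te = random_te_library(1, 1000, seed=55)["TY1"]
        with_te = mutated[:breakpoint_] + te + mutated[breakpoint_:]
        assert snp_distance(self._asm(seq), self._asm(with_te)) == k

    def test_unrelated_sequences_raise(self, rng):
        a = self._asm(random_sequence(5000, rng))
        b = self._asm(random_sequence(5000, np.random.default_rng(2)))
        with pytest.raises(ValueError, match="no homologous"):
            snp_distance(a, b)


class TestConcordance:
    def test_monotone_decrease_gives_negative_r(self):
        shared = {("A", f"S{i}"): 1.0 - 0.1 * i for i in range(6)}
        snp = {("A", f"S{i}"): 100 * i + 10 for i in range(6)}
        r, n = distance_concordance(shared, snp)
        assert r < 0 and n == 6

    def test_exact_line_gives_minus_one(self):
        shared = {("A", f"S{i}"): 0.9 - 0.1 * i for i in range(4)}
        snp = {("A", f"S{i}"): 50 + 100 * i for i in range(4)}
        r, _ = distance_concordance(shared, snp)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        shared = {("A", f"S{i}"): 0.5 for i in range(4)}
        snp = {("A", f"S{i}"): 100 * i for i in range(4)}
        with pytest.raises(ValueError, match="variance"):
            distance_concordance(shared, snp)

    def test_spearman_available(self):
        shared = {("A", f"S{i}"): 1.0 / (1 + i) for i in range(5)}
        snp = {("A", f"S{i}"): 10 * i for i in range(5)}
        r, _ = distance_concordance(shared, snp, method="spearman")
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            distance_concordance(
                {("A", "B"): 0.5, ("A", "C"): 0.4},
                {("A", "B"): 10, ("A", "C"): 20},
            )
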