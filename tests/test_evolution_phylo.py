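"""Poisson distances, neighbor-joining and bootstrap support."""

import math

import dendropy
import numpy as np
import pytest

from xylpscan.core_io import Msa
from xylpscan.evolution import (
    DistanceMatrix, bootstrap_support, nj_tree, poisson_distance,
    tree_bipartitions,
)
from xylpscan.synthetic_data import gen_msa_on_tree

from oracles import tree_path_lengths


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        msa = Msa(("a", "b"), ("ACDEF", "ACDEF"))
        assert poisson_distance(msa).get("a", "b") == 0.0

    def test_half_mismatch_closed_form(self):
        msa = Msa(("a", "b"), ("AAAA", "AAGG"))
        assert poisson_distance(msa).get("a", "b") == pytest.approx(math.log(2))

    def test_pairwise_deletion_hand_count(self):
        # shared ungapped sites: positions 1, 2, 4 -> 3 sites, 0 mismatches
        msa = Msa(("a", "b"), ("AC-A", "ACGA"))
        assert poisson_distance(msa).get("a", "b") == 0.0
        # one mismatch over the same 3 shared sites
        msa2 = Msa(("a", "b"), ("AC-T", "ACGA"))
        assert poisson_distance(msa2).get("a", "b") == pytest.approx(
            -math.log(1 - 1 / 3))

    def test_no_shared_sites_error_names_pair(self):
        msa = Msa(("a", "b"), ("A--", "-GG"))
        with pytest.raises(ValueError, match="a.*b"):
            poisson_distance(msa)

    def test_saturated_pair_capped_and_flagged(self):
        msa = Msa(("a", "b"), ("AAAA", "GGGG"))
        dm = poisson_distance(msa, cap=7.5)
        assert dm.get("a", "b") == 7.5
        assert ("a", "b") in dm.saturated

    def test_correction_never_below_p(self):
        rng = np.random.default_rng(0)
        for p in rng.uniform(0.01, 0.99, size=50):
            assert -math.log(1 - p) >= p


def _additive_matrix_from_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    return DistanceMatrix(tuple(taxa), tree_path_lengths(tree, taxa)), tree


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                      [4, 4, 0, 2], [4, 4, 2, 0]], float)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        tree = nj_tree(dm)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        paths = tree_path_lengths(tree, ("A", "B", "C", "D"))
        assert np.allclose(paths, d, atol=1e-9)
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node and not e.head_node.is_leaf()
                    and e.tail_node is not None]
        assert internal == [2.0]

    def test_three_taxa_exact(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        dm = DistanceMatrix(("A", "B", "C"), d)
        paths = tree_path_lengths(nj_tree(dm), ("A", "B", "C"))
        assert np.allclose(paths, d, atol=1e-9)

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(1)
        newick = "((A:1.2,B:0.7):0.5,(C:0.9,(D:0.4,E:1.1):0.3):0.6,F:2.0);"
        dm, _ = _additive_matrix_from_tree(newick)
        base = tree_bipartitions(nj_tree(dm))
        for _ in range(3):
            perm = rng.permutation(len(dm.taxa))
            dm2 = DistanceMatrix(
                tuple(dm.taxa[i] for i in perm), dm.d[np.ix_(perm, perm)]
            )
            assert tree_bipartitions(nj_tree(dm2)) == base

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_reproduced_up_to_8_taxa(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]

        def random_subtree(labels):
            if len(labels) == 1:
                return f"{labels[0]}:{rng.uniform(0.1, 2.0):.6f}"
            k = int(rng.integers(1, len(labels)))
            left, right = labels[:k], labels[k:]
            return (f"({random_subtree(left)},{random_subtree(right)})"
                    f":{rng.uniform(0.1, 2.0):.6f}")

        newick = f"({random_subtree(taxa)});"
        sim = dendropy.Tree.get(data=newick, schema="newick")
        dm = DistanceMatrix(tuple(sorted(taxa)),
                            tree_path_lengths(sim, sorted(taxa)))
        tree = nj_tree(dm)
        paths = tree_path_lengths(tree, sorted(taxa))
        assert np.allclose(paths, dm.d, atol=1e-9)

    def test_cross_check_against_skbio(self):
        import skbio
        rng = np.random.default_rng(5)
        newick = "((A:1.0,B:0.5):0.4,(C:0.8,D:0.6):0.7,(E:1.2,F:0.9):0.2);"
        dm, _ = _additive_matrix_from_tree(newick)
        ours = tree_bipartitions(nj_tree(dm))
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=list(dm.taxa)))
        sk_dp = dendropy.Tree.get(data=str(sk), schema="newick")
        assert tree_bipartitions(sk_dp) == ours

    def test_non_symmetric_matrix_error(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), d)

    def test_negative_branches_clamped(self):
        # strongly non-additive matrix can force negative NJ branch lengths
        d = np.array([
            [0, 1, 8, 8], [1, 0, 1, 8], [8, 1, 0, 1], [8, 8, 1, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        assert all((e.length or 0) >= 0 for e in tree.preorder_edge_iter())


FIVE_TAXON = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.3);"


class TestBootstrap:
    def _msa(self, seed=0, length=800):
        tree = dendropy.Tree.get(data=FIVE_TAXON, schema="newick")
        return gen_msa_on_tree(seed, tree, length)

    def test_same_seed_identical_supports(self):
        msa = self._msa()
        t1 = bootstrap_support(msa, B=25, seed=42)
        t2 = bootstrap_support(msa, B=25, seed=42)
        labels = lambda t: sorted(
            n.label for n in t.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        )
        assert labels(t1) == labels(t2)

    def test_single_replicate_supports_binary(self):
        msa = self._msa(seed=1)
        tree = bootstrap_support(msa, B=1, seed=0)
        sups = [n.support for n in tree.preorder_node_iter()
                if hasattr(n, "support")]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_unambiguous_split_gets_full_support(self):
        # two identical-sequence clades separated by a long branch
        row1 = "A" * 120
        row2 = "C" * 60 + "G" * 60
        msa = Msa(("a1", "a2", "b1", "b2"),
                  (row1, row1, row2, row2))
        tree = bootstrap_support(msa, B=50, seed=0)
        sups = [n.support for n in tree.preorder_node_iter()
                if hasattr(n, "support")]
        assert sups == [100.0]

    def test_b_below_one_error(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._msa(), B=0)


class TestTopologyRecovery:
    def test_recovery_improves_with_length(self):
        tree = dendropy.Tree.get(data=FIVE_TAXON, schema="newick")
        truth = tree_bipartitions(nj_tree(poisson_distance(
            gen_msa_on_tree(0, tree, 4000))))

        def rate(length, n=15):
            hits = 0
            for seed in range(n):
                msa = gen_msa_on_tree(seed, tree, length)
                if tree_bipartitions(nj_tree(poisson_distance(msa))) == truth:
                    hits += 1
            return hits / n

        assert rate(1500) >= rate(60) - 0.2  # monotone trend, with slack
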