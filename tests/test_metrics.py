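"""Alignment metrics and tree-distance implementations vs oracles."""

import io as _io
import itertools

import dendropy
import numpy as np
import pytest
from skbio import TreeNode

from crowdalign.io import Msa, ValidationError
from crowdalign.metrics import (
    compound_distance,
    gap_frequencies,
    kc_distance,
    kc_vector,
    sampled_gap_stats,
    sampled_tree_distance,
    sum_of_pairs,
    triplet_distance,
)
from conftest import random_rooted_newick


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def dendropy_triplet_distance(n1: str, n2: str) -> int:
    """Independent per-triple MRCA comparison through dendropy."""
    taxa = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=taxa,
                           rooting="force-rooted")
    t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=taxa,
                           rooting="force-rooted")
    for t in (t1, t2):
        t.encode_bipartitions()
    names = sorted(x.taxon.label for x in t1.leaf_node_iter())

    def cherry(tree, a, b, c):
        depths = {}
        for node in tree.preorder_node_iter():
            depths[node] = 0 if node.parent_node is None else depths[node.parent_node] + 1
        pdm = {}
        for x, y in itertools.combinations((a, b, c), 2):
            mrca = tree.mrca(taxon_labels=[x, y])
            pdm[frozenset((x, y))] = depths[mrca]
        items = sorted(pdm.items(), key=lambda kv: -kv[1])
        if items[0][1] == items[2][1]:
            return None  # unresolved
        return items[0][0]

    diff = 0
    for a, b, c in itertools.combinations(names, 3):
        if cherry(t1, a, b, c) != cherry(t2, a, b, c):
            diff += 1
    return diff


class TestSumOfPairs:
    def test_hand_counted_example(self, toy_msa):
        # columns: AAA (3 pairs) CCC (3) -G- (0) UUU (3)
        assert sum_of_pairs(toy_msa) == 9

    def test_single_sequence_is_zero(self):
        assert sum_of_pairs(Msa(("a",), ("ACGU",))) == 0

    def test_row_permutation_invariance(self, toy_msa):
        permuted = Msa(("c", "a", "b"),
                       (toy_msa.rows[2], toy_msa.rows[0], toy_msa.rows[1]))
        assert sum_of_pairs(permuted) == sum_of_pairs(toy_msa)

    def test_gap_fraction_filter_excludes_heavy_columns(self):
        msa = Msa(("a", "b", "c"), ("A--U", "A--U", "A-GU"))
        assert sum_of_pairs(msa, gap_fraction_max=0.5) == 6  # cols 0 and 3

    def test_top_k_filter_monotone_in_k(self, toy_msa):
        values = [
            sum_of_pairs(toy_msa, top_k_populated=k) for k in range(1, 5)
        ]
        assert values == sorted(values)
        assert values[-1] == sum_of_pairs(toy_msa)

    def test_filter_modes_are_exclusive(self, toy_msa):
        with pytest.raises(ValidationError):
            sum_of_pairs(toy_msa, gap_fraction_max=0.5, top_k_populated=2)


class TestGapStats:
    def test_per_column_fractions(self, toy_msa):
        freqs = gap_frequencies(toy_msa)
        assert freqs == pytest.approx([0, 0, 2 / 3, 0])
        n_rows = len(toy_msa.ids)
        total_gaps = sum(r.count("-") for r in toy_msa.rows)
        assert freqs.sum() * n_rows == pytest.approx(total_gaps)

    def test_full_subsample_has_no_variance(self, toy_msa):
        stats = sampled_gap_stats(toy_msa, subsample_size=3, n_samples=10,
                                  rng=np.random.default_rng(0))
        assert np.allclose(stats.samples, stats.samples[0])

    def test_gapless_alignment_all_zero(self):
        msa = Msa(("a", "b"), ("ACGU", "ACGU"))
        stats = sampled_gap_stats(msa, subsample_size=2, n_samples=5,
                                  rng=np.random.default_rng(0))
        assert np.all(stats.samples == 0)

    def test_oversized_subsample_rejected(self, toy_msa):
        with pytest.raises(ValidationError):
            sampled_gap_stats(toy_msa, subsample_size=10, n_samples=2,
                              rng=np.random.default_rng(0))


class TestKendallColijn:
    def test_three_leaf_vectors(self):
        v1 = kc_vector(_tree("((a,b),c);"), ["a", "b", "c"])
        v2 = kc_vector(_tree("(a,(b,c));"), ["a", "b", "c"])
        assert list(v1) == [1, 0, 0, 1, 1, 1]
        assert list(v2) == [0, 0, 1, 1, 1, 1]
        assert kc_distance(_tree("((a,b),c);"), _tree("(a,(b,c));")) == (
            pytest.approx(np.sqrt(2))
        )

    def test_star_tree_pairs_are_zero(self):
        v = kc_vector(_tree("(a,b,c);"), ["a", "b", "c"])
        assert list(v) == [0, 0, 0, 1, 1, 1]

    def test_vector_length(self):
        rng = np.random.default_rng(1)
        t = _tree(random_rooted_newick(7, rng))
        v = kc_vector(t, [f"L{i}" for i in range(7)])
        assert len(v) == 7 * 6 // 2 + 7

    def test_lambda_blends_branch_lengths(self):
        t = _tree("((a:1,b:2):0.5,c:3);")
        v0 = kc_vector(t, ["a", "b", "c"], lam=0.0)
        v1 = kc_vector(t, ["a", "b", "c"], lam=1.0)
        assert list(v0) == [1, 0, 0, 1, 1, 1]
        assert list(v1) == [0.5, 0, 0, 1, 2, 3]

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _tree(random_rooted_newick(8, rng))
            b = _tree(random_rooted_newick(8, rng))
            assert kc_distance(a, a) == 0
            assert kc_distance(a, b) == pytest.approx(kc_distance(b, a))

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValidationError):
            kc_vector(_tree("((a,b),c);"), ["a", "z"])


class TestTriplet:
    def test_three_leaf_example(self):
        assert triplet_distance(_tree("((a,b),c);"), _tree("(a,(b,c));")) == 1
        assert triplet_distance(_tree("((a,b),c);"), _tree("((a,b),c);")) == 0

    def test_polytomy_differs_from_resolved(self):
        assert triplet_distance(_tree("(a,b,c);"), _tree("((a,b),c);")) == 1
        assert triplet_distance(_tree("(a,b,c);"), _tree("(a,b,c);")) == 0

    def test_bounded_by_triple_count(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _tree(random_rooted_newick(7, rng))
            b = _tree(random_rooted_newick(7, rng))
            assert 0 <= triplet_distance(a, b) <= 35  # C(7,3)

    def test_matches_dendropy_mrca_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n1 = random_rooted_newick(10, rng)
            n2 = random_rooted_newick(10, rng)
            assert triplet_distance(_tree(n1), _tree(n2)) == (
                dendropy_triplet_distance(n1, n2)
            )

    def test_tip_cap_enforced(self):
        rng = np.random.default_rng(5)
        a = _tree(random_rooted_newick(12, rng))
        with pytest.raises(ValidationError):
            triplet_distance(a, a, cap=10)


class TestSampledProtocol:
    def test_identical_trees_have_zero_mean(self):
        rng = np.random.default_rng(6)
        t = _tree(random_rooted_newick(30, rng, with_lengths=True))
        for metric in ("kendall_colijn", "triplet"):
            report = sampled_tree_distance(
                t, t.copy(), metric, n_tips=10, n_reps=3,
                rng=np.random.default_rng(0),
            )
            assert report.mean == 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        a = _tree(random_rooted_newick(30, rng, with_lengths=True))
        b = _tree(random_rooted_newick(30, rng, with_lengths=True))
        r1 = sampled_tree_distance(a, b, "kendall_colijn", n_tips=12,
                                   n_reps=4, rng=np.random.default_rng(9))
        r2 = sampled_tree_distance(a, b, "kendall_colijn", n_tips=12,
                                   n_reps=4, rng=np.random.default_rng(9))
        assert r1 == r2

    def test_insufficient_tips_rejected(self):
        rng = np.random.default_rng(8)
        a = _tree(random_rooted_newick(5, rng))
        with pytest.raises(ValidationError):
            sampled_tree_distance(a, a.copy(), "triplet", n_tips=10, n_reps=1,
                                  rng=np.random.default_rng(0))


class TestCompound:
    def test_scaled_average_formula(self):
        out = compound_distance({"m1": 10, "m2": 20}, {"m1": 1, "m2": 4})
        assert out == pytest.approx({"m1": 0.375, "m2": 1.0})

    def test_single_method_scales_to_one(self):
        assert compound_distance({"m": 3.0}, {"m": 7.0}) == {"m": 1.0}

    def test_method_with_both_minima_is_smallest(self):
        out = compound_distance({"a": 1, "b": 5, "c": 3},
                                {"a": 2, "b": 9, "c": 4})
        assert min(out, key=out.get) == "a"

    def test_mismatched_methods_rejected(self):
        with pytest.raises(ValidationError):
            compound_distance({"a": 1}, {"b": 1})
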