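import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from passar import (
    AbundanceTable,
    PhyloTree,
    decompose_beta,
    pairwise_decompose,
    random_tree,
    read_newick,
    summarize_decomposition,
    unifrac_matrix,
    unweighted_unifrac,
    weighted_unifrac,
    write_newick,
)
from passar.beta_diversity import DistanceMatrix
from passar.errors import EmptyTableError, InvalidSpecError, TaxonTreeMismatchError

from ._oracles import unifrac_path_oracle


# ---------------------------------------------------------------------------
# Replacement / richness-difference decomposition
# ---------------------------------------------------------------------------

class TestDecomposeBeta:
    def test_identical_communities(self):
        for fam in ("jaccard", "sorensen"):
            t = decompose_beta([1, 1, 0], [2, 3, 0], fam)
            assert (t.similarity, t.replacement, t.richness_difference) == (1.0, 0.0, 0.0)

    def test_disjoint_equal_richness_jaccard(self):
        t = decompose_beta([1, 1, 0, 0], [0, 0, 1, 1], "jaccard")
        assert (t.similarity, t.replacement, t.richness_difference) == (0.0, 1.0, 0.0)

    def test_worked_triplet_a2_b1_c3(self):
        x = [1, 1, 1, 0, 0, 0]  # a=2 shared with y, b=1 unique
        y = [1, 1, 0, 1, 1, 1]  # c=3 unique
        j = decompose_beta(x, y, "jaccard")
        assert j.similarity == pytest.approx(1 / 3)
        assert j.replacement == pytest.approx(1 / 3)
        assert j.richness_difference == pytest.approx(1 / 3)
        s = decompose_beta(x, y, "sorensen")
        assert (s.similarity, s.replacement, s.richness_difference) == (0.5, 0.25, 0.25)

    def test_counts_binarized(self):
        a = decompose_beta([5, 0, 2], [1, 1, 0], "jaccard")
        b = decompose_beta([1, 0, 1], [9, 4, 0], "jaccard")
        assert (a.similarity, a.replacement, a.richness_difference) == (
            b.similarity,
            b.replacement,
            b.richness_difference,
        )

    def test_both_empty(self):
        with pytest.raises(EmptyTableError):
            decompose_beta([0, 0], [0, 0], "jaccard")

    def test_unknown_family(self):
        with pytest.raises(InvalidSpecError):
            decompose_beta([1], [1], "baselga")

    @given(
        x=arrays(np.int64, 15, elements=st.integers(0, 3)),
        y=arrays(np.int64, 15, elements=st.integers(0, 3)),
    )
    @settings(max_examples=200, deadline=None)
    def test_closure_and_family_order(self, x, y):
        if (x > 0).sum() + (y > 0).sum() == 0:
            return
        tj = decompose_beta(x, y, "jaccard")
        ts = decompose_beta(x, y, "sorensen")
        for t in (tj, ts):
            assert abs(t.similarity + t.replacement + t.richness_difference - 1.0) < 1e-12
            assert 0.0 <= min(t.similarity, t.replacement, t.richness_difference)
        assert tj.dissimilarity >= ts.dissimilarity - 1e-12
        if 0 < tj.dissimilarity < 1:
            assert tj.dissimilarity > ts.dissimilarity

    def test_nestedness_limit(self):
        # x subset of y: pure richness difference
        t = decompose_beta([1, 1, 0, 0], [1, 1, 1, 1], "jaccard")
        assert t.replacement == 0.0
        assert t.dissimilarity == pytest.approx(t.richness_difference)


class TestSummarize:
    def test_single_pair_contribution(self):
        from passar.beta_diversity import BetaTriplet

        crafted = BetaTriplet(("a", "b"), "jaccard", 0.5, 0.4, 0.1)
        s = summarize_decomposition([crafted])
        assert s.replacement_contribution_pct == pytest.approx(80.0)
        assert s.richness_difference_contribution_pct == pytest.approx(20.0)

    def test_degenerate_all_identical(self):
        t = decompose_beta([1, 1], [1, 1], "jaccard")
        s = summarize_decomposition([t, t])
        assert s.replacement_contribution_pct is None
        assert s.mean_similarity == 1.0

    def test_mixed_families_rejected(self):
        a = decompose_beta([1, 0], [0, 1], "jaccard")
        b = decompose_beta([1, 0], [0, 1], "sorensen")
        with pytest.raises(InvalidSpecError):
            summarize_decomposition([a, b])

    def test_empty_rejected(self):
        with pytest.raises(InvalidSpecError):
            summarize_decomposition([])

    def test_rare_dominated_pool_replacement_majority(self, sim_table):
        # equal-area passive samples from a long-tailed pool: replacement
        # dominates the dissimilarity
        _, _, table, _ = sim_table
        for fam in ("sorensen", "jaccard"):
            s = summarize_decomposition(pairwise_decompose(table, fam))
            assert s.n_pairs == 28
            assert s.replacement_contribution_pct > 50.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _balanced_four_leaf() -> PhyloTree:
    return PhyloTree.from_newick("((L1:1,L2:1):1,(L3:1,L4:1):1):0;")


class TestPhyloTree:
    def test_newick_roundtrip(self, tmp_path):
        tree = random_tree([f"t{i}" for i in range(7)], seed=5)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)
        assert back.to_newick() == tree.to_newick()

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhyloTree.from_newick("((a:1,a:1):1,b:1):0;")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhyloTree.from_newick("((a:1,b),c:1);")

    def test_multifurcating_accepted(self):
        tree = PhyloTree.from_newick("(a:1,b:1,c:2):0;")
        assert tree.n_leaves == 3


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

class TestUniFrac:
    def test_identical_presence_unweighted_zero(self):
        tree = _balanced_four_leaf()
        assert unweighted_unifrac(tree, {"L1": 1, "L3": 2}, {"L1": 5, "L3": 1}) == 0.0

    def test_two_leaf_fully_separated(self):
        tree = PhyloTree.from_newick("(a:1,b:1):0;")
        assert unweighted_unifrac(tree, {"a": 3}, {"b": 2}) == 1.0
        assert weighted_unifrac(tree, {"a": 3}, {"b": 2}, normalized=True) == 1.0
        assert weighted_unifrac(tree, {"a": 3}, {"b": 2}, normalized=False) == pytest.approx(2.0)

    def test_balanced_tree_one_sided(self):
        # x = {L1, L2}, y = {L3}: every covered branch is unique to one side
        # (including the internal edge above L3), so the distance is 1.
        tree = _balanced_four_leaf()
        x, y = {"L1": 1, "L2": 1}, {"L3": 1}
        d = unweighted_unifrac(tree, x, y)
        assert d == pytest.approx(unifrac_path_oracle(tree.root, x, y, "unweighted"), abs=1e-12)
        assert d == 1.0

    def test_weighted_identical_composition(self):
        tree = _balanced_four_leaf()
        x = {"L1": 2, "L2": 2}
        y = {"L1": 10, "L2": 10}
        assert weighted_unifrac(tree, x, y) == pytest.approx(0.0, abs=1e-12)
        assert weighted_unifrac(tree, x, y, normalized=False) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_scale_invariance(self):
        tree = _balanced_four_leaf()
        x = {"L1": 1, "L2": 3, "L3": 1}
        y = {"L2": 2, "L4": 5}
        x10 = {k: 10 * v for k, v in x.items()}
        for norm in (True, False):
            assert weighted_unifrac(tree, x, y, norm) == pytest.approx(
                weighted_unifrac(tree, x10, y, norm), abs=1e-12
            )

    def test_taxon_missing_from_tree(self):
        tree = _balanced_four_leaf()
        with pytest.raises(TaxonTreeMismatchError):
            unweighted_unifrac(tree, {"L1": 1, "zzz": 1}, {"L2": 1})

    def test_empty_community(self):
        tree = _balanced_four_leaf()
        with pytest.raises(EmptyTableError):
            weighted_unifrac(tree, {}, {"L1": 1})

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5, 6])
    def test_matches_path_oracle_random(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        ids = [f"t{i}" for i in range(n_leaves)]
        for rep in range(20):
            tree = random_tree(ids, seed=100 * n_leaves + rep)
            x = {t: int(c) for t, c in zip(ids, rng.integers(0, 5, n_leaves))}
            y = {t: int(c) for t, c in zip(ids, rng.integers(0, 5, n_leaves))}
            if sum(x.values()) == 0 or sum(y.values()) == 0:
                continue
            assert unweighted_unifrac(tree, x, y) == pytest.approx(
                unifrac_path_oracle(tree.root, x, y, "unweighted"), abs=1e-12
            )
            for norm in (True, False):
                assert weighted_unifrac(tree, x, y, norm) == pytest.approx(
                    unifrac_path_oracle(tree.root, x, y, "weighted", norm), abs=1e-12
                )

    def test_metric_axioms_on_random_triples(self):
        # Symmetry, zero self-distance and [0,1] bounds hold for both
        # variants. The triangle inequality is asserted for unweighted and
        # RAW weighted UniFrac, which are true metrics; the NORMALIZED
        # weighted variant is not one (its pair-dependent denominator admits
        # small violations, observed at the 6e-3 level on random triples).
        rng = np.random.default_rng(7)
        ids = [f"t{i}" for i in range(6)]
        for rep in range(1, 201):
            tree = random_tree(ids, seed=rep)
            comms = []
            for _ in range(3):
                c = {t: int(v) for t, v in zip(ids, rng.integers(0, 4, 6))}
                if sum(c.values()) == 0:
                    c[ids[0]] = 1
                comms.append(c)
            metrics = {
                "unweighted": lambda a, b: unweighted_unifrac(tree, a, b),
                "weighted_norm": lambda a, b: weighted_unifrac(tree, a, b, normalized=True),
                "weighted_raw": lambda a, b: weighted_unifrac(tree, a, b, normalized=False),
            }
            for name, d in metrics.items():
                for a, b in itertools.combinations(comms, 2):
                    assert d(a, b) == pytest.approx(d(b, a), abs=1e-12)
                    if name != "weighted_raw":
                        assert 0.0 <= d(a, b) <= 1.0 + 1e-12
                for a in comms:
                    assert d(a, a) == pytest.approx(0.0, abs=1e-12)
                if name == "weighted_norm":
                    continue
                d01, d02, d12 = d(comms[0], comms[1]), d(comms[0], comms[2]), d(comms[1], comms[2])
                assert d01 <= d02 + d12 + 1e-9
                assert d02 <= d01 + d12 + 1e-9
                assert d12 <= d01 + d02 + 1e-9


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(InvalidSpecError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [0.5, 0.0]]), "x")
        with pytest.raises(InvalidSpecError):
            DistanceMatrix(("a", "b"), np.array([[0.1, 1.0], [1.0, 0.0]]), "x")

    def test_unifrac_matrix(self):
        counts = np.array([[3, 1, 0, 0], [0, 2, 2, 0], [1, 0, 0, 4]])
        table = AbundanceTable(("s1", "s2", "s3"), ("L1", "L2", "L3", "L4"), counts)
        tree = _balanced_four_leaf()
        for metric in ("unweighted", "weighted"):
            dm = unifrac_matrix(tree, table, metric=metric)
            v = dm.values
            assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
            assert np.all(v >= 0) and np.all(v <= 1.0 + 1e-12)
            assert dm.metric.endswith("unifrac")
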