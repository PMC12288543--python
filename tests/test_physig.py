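"""Phylogenetic-signal indices, correlograms, and controlled traits."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from plastcov.physig import (
    TraitVector,
    blomberg_K,
    correlogram,
    morans_I,
    patristic_matrix,
    randomize_trait,
    read_tree,
    simulate_bm_trait,
    vcv_matrix,
)
from plastcov.simulate import simulate_tree_and_traits, yule_tree


def _brute_force_patristic(tree):
    """Independent oracle: path sums via root paths per tip pair."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[labels[i]]
            pj = set(id(x) for x in paths[labels[j]])
            mrca = next(x for x in pi if id(x) in pj)
            d = 0.0
            for lab in (labels[i], labels[j]):
                node = paths[lab][0]
                while node is not mrca:
                    d += node.edge.length or 0.0
                    node = node.parent_node
            D[i, j] = D[j, i] = d
    return labels, D


class TestPatristic:
    def test_two_tip_tree(self):
        tree = read_tree("(A:1,B:2);")
        labels, D = patristic_matrix(tree)
        assert labels == ["A", "B"]
        assert D[0, 1] == pytest.approx(3.0)

    def test_balanced_ultrametric(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        labels, D = patristic_matrix(tree)
        i = {lab: k for k, lab in enumerate(labels)}
        assert D[i["A"], i["B"]] == pytest.approx(2.0)
        assert D[i["A"], i["C"]] == pytest.approx(4.0)  # 2h with h = 2

    def test_matches_brute_force_oracle_on_random_trees(self):
        for seed in range(20):
            tree = yule_tree(10, seed)
            labels, D = patristic_matrix(tree)
            labels_o, D_o = _brute_force_patristic(tree)
            assert labels == labels_o
            np.testing.assert_allclose(D, D_o, atol=1e-10)

    def test_negative_branch_length_rejected(self):
        tree = read_tree("(A:1,B:-2);")
        with pytest.raises(ValueError, match="negative"):
            patristic_matrix(tree)

    def test_vcv_consistency(self):
        """C_ii equals tip depth; C_ij + D_ij/2 * 2 = r_i + r_j."""
        tree = yule_tree(12, 3)
        labels, C = vcv_matrix(tree)
        _, D = patristic_matrix(tree)
        # ultrametric depth-1 tree: diagonal 1, and C_ij = 1 - D_ij/2
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)
        np.testing.assert_allclose(C, 1.0 - D / 2.0, atol=1e-9)


class TestMoran:
    def test_null_expectation_minus_one_over_n_minus_1(self):
        """Mean I over many random permutations approximates -1/(n-1)."""
        tree = yule_tree(50, 5)
        rng = np.random.default_rng(0)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        x = rng.standard_normal(50)
        from plastcov.physig import _moran_stat_many, _row_normalized_inverse
        _, D = patristic_matrix(tree)
        W = _row_normalized_inverse(D)
        perms = np.array([rng.permutation(x) for _ in range(1000)]).T
        mean_I = _moran_stat_many(perms, W).mean()
        assert mean_I == pytest.approx(-1 / 49, abs=0.01)

    def test_constant_trait_errors(self):
        tree = yule_tree(10, 1)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        with pytest.raises(ValueError, match="variance"):
            morans_I(TraitVector(pd.Series(1.0, index=labels)), tree, n_perm=0)

    def test_orphan_tips_rejected(self):
        tree = yule_tree(10, 1)
        with pytest.raises(ValueError, match="not in tree"):
            morans_I(TraitVector(pd.Series({"nope": 1.0, "T1": 2.0,
                                            "T2": 0.5, "T3": 1.5})), tree)

    def test_bm_trait_detected(self):
        hits = 0
        for seed in range(20):
            tree, trait = simulate_tree_and_traits(60, "bm", seed)
            i_obs, p = morans_I(trait, tree, n_perm=199, seed=seed)
            hits += p < 0.05
        assert hits >= 16  # strong signal detected in most runs


class TestBlomberg:
    def test_affine_invariance(self):
        tree, trait = simulate_tree_and_traits(40, "bm", 9)
        a = blomberg_K(trait, tree, n_perm=0)
        shifted = TraitVector(trait.values * 3.7 - 11.0)
        b = blomberg_K(shifted, tree, n_perm=0)
        assert b.K == pytest.approx(a.K, rel=1e-9)
        assert b.K_star == pytest.approx(a.K_star, rel=1e-9)
        assert b.I == pytest.approx(a.I, rel=1e-9)

    def test_white_noise_K_below_one(self):
        ks = []
        for seed in range(15):
            tree, trait = simulate_tree_and_traits(60, "white", seed)
            ks.append(blomberg_K(trait, tree, n_perm=0).K)
        assert np.median(ks) < 1.0

    def test_star_tree_p_not_degenerate(self):
        """A star tree has no structure; permutation p is non-extreme."""
        newick = "(" + ",".join(f"T{i}:1.0" for i in range(1, 21)) + ");"
        tree = read_tree(newick)
        rng = np.random.default_rng(3)
        labels = [f"T{i}" for i in range(1, 21)]
        trait = TraitVector(pd.Series(rng.standard_normal(20), index=labels))
        idx = blomberg_K(trait, tree, n_perm=199, seed=1)
        assert 0.05 < idx.p_K  # nothing to detect

    def test_missing_tips_pruned_pairwise(self):
        tree, trait = simulate_tree_and_traits(30, "bm", 2)
        vals = trait.values.copy()
        vals.iloc[:5] = np.nan
        idx = blomberg_K(TraitVector(vals), tree, n_perm=0)
        assert idx.n == 25


class TestControlledTraits:
    def test_randomized_preserves_moments_and_missing(self):
        tree, trait = simulate_tree_and_traits(30, "white", 4)
        vals = trait.values.copy()
        vals.iloc[[3, 7]] = np.nan
        src = TraitVector(vals)
        rnd = randomize_trait(src, seed=8)
        assert rnd.kind == "randomized"
        assert rnd.values.isna().equals(src.values.isna())
        assert sorted(rnd.non_missing()) == pytest.approx(
            sorted(src.non_missing()))
        assert rnd.non_missing().mean() == pytest.approx(src.non_missing().mean())

    def test_two_seeds_differ(self):
        tree, trait = simulate_tree_and_traits(30, "white", 4)
        a = randomize_trait(trait, seed=1).values
        b = randomize_trait(trait, seed=2).values
        assert not a.equals(b)

    def test_bm_trait_matches_empirical_moments(self):
        tree, trait = simulate_tree_and_traits(40, "white", 6)
        bm = simulate_bm_trait(tree, seed=10, match=trait)
        assert bm.kind == "enforced_bm"
        assert bm.non_missing().mean() == pytest.approx(
            trait.non_missing().mean(), abs=1e-10)
        assert bm.non_missing().std(ddof=1) == pytest.approx(
            trait.non_missing().std(ddof=1), abs=1e-10)

    def test_bm_trait_seed_deterministic(self):
        tree, _ = simulate_tree_and_traits(20, "white", 6)
        a = simulate_bm_trait(tree, seed=5).values
        b = simulate_bm_trait(tree, seed=5).values
        assert a.equals(b)

    def test_zero_depth_tree_rejected(self):
        tree = read_tree("(A:0,B:0);")
        with pytest.raises(ValueError, match="depth"):
            simulate_bm_trait(tree, seed=1)


class TestCorrelogram:
    def test_no_bootstrap_gives_nan_cis(self):
        tree, trait = simulate_tree_and_traits(40, "bm", 12)
        res = correlogram(trait, tree, n_classes=10, n_boot=0, seed=1)
        assert np.isnan(res.ci_low).all() and np.isnan(res.ci_high).all()
        assert len(res.class_mid) == 10
        assert (np.diff(res.class_mid) > 0).all()

    def test_sparse_classes_reported_na(self):
        tree, trait = simulate_tree_and_traits(12, "bm", 13)
        res = correlogram(trait, tree, n_classes=30, n_boot=0, min_pairs=10)
        assert np.isnan(res.I).any()
        assert "na" in res.flag

    def test_ci_brackets_point_estimate(self):
        tree, trait = simulate_tree_and_traits(50, "bm", 14)
        res = correlogram(trait, tree, n_classes=8, n_boot=60, seed=2)
        ok = np.isfinite(res.I) & np.isfinite(res.ci_low)
        # bootstrap percentile CIs usually bracket the estimate
        frac = np.mean((res.ci_low[ok] <= res.I[ok] + 0.1)
                       & (res.I[ok] - 0.1 <= res.ci_high[ok]))
        assert frac >= 0.7

    def test_bm_smallest_class_positive(self):
        hits = 0
        for seed in range(10):
            tree, trait = simulate_tree_and_traits(60, "bm", seed + 100)
            res = correlogram(trait, tree, n_classes=10, n_boot=60, seed=seed)
            first = next(i for i in range(10) if np.isfinite(res.I[i]))
            hits += res.flag[first] == "+"
        assert hits >= 8


class TestYule:
    def test_same_seed_same_newick(self):
        a = yule_tree(25, 7).as_string(schema="newick")
        b = yule_tree(25, 7).as_string(schema="newick")
        assert a == b

    def test_unit_depth_ultrametric(self):
        tree = yule_tree(30, 11)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)
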