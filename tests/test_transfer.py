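import numpy as np
import pytest
from scipy.spatial.distance import pdist

import driversel as d
from driversel.transfer import InsufficientTargetError


def mean_pair_dist(rows):
    return 0.0 if len(rows) < 2 else float(pdist(rows).mean())


def sum_pair_dist(rows):
    return 0.0 if len(rows) < 2 else float(pdist(rows).sum())


def brute_prune(node, T, idx):
    """Oracle: independently evaluate the snip rule at every internal node."""
    if node.feature is None or len(idx) < 2:
        return node.copy()
    d_i = mean_pair_dist(T[idx])
    mask = T[idx, node.feature] <= node.threshold
    ia, ib = idx[mask], idx[~mask]
    if d_i < mean_pair_dist(T[ia]) and d_i < mean_pair_dist(T[ib]):
        return node.as_leaf()
    out = node.copy()
    out.left = brute_prune(node.left, T, ia)
    out.right = brute_prune(node.right, T, ib)
    return out


def brute_shift(node, T, idx):
    """Oracle: exhaustive candidate-grid minimization of the within-child
    pair-distance sum at every internal node, top-down."""
    if node.feature is None:
        return node.copy()
    out = node.copy()
    t0 = node.threshold
    if len(idx) >= 2:
        vals = np.unique(T[idx, node.feature])
        cands = [t0] + [0.5 * (vals[i] + vals[i + 1]) for i in range(len(vals) - 1)]
        best = None
        for c in cands:
            mask = T[idx, node.feature] <= c
            key = (sum_pair_dist(T[idx[mask]]) + sum_pair_dist(T[idx[~mask]]), abs(c - t0), c)
            if best is None or key < best:
                best = key
        out.threshold = best[2]
    mask = T[idx, node.feature] <= out.threshold
    out.left = brute_shift(node.left, T, idx[mask])
    out.right = brute_shift(node.right, T, idx[~mask])
    return out


def random_instances(n_instances, seed, n_features=4, max_targets=50):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(8, 40))
        X = rng.normal(size=(n, n_features))
        y = rng.integers(0, 3, size=n)
        if np.unique(y).size < 2:
            continue
        tree = d.train_tree(X, y, d.TrainConfig(m_features=n_features, min_leaf=2), rng)
        T = rng.normal(size=(int(rng.integers(0, max_targets)), n_features))
        yield tree, T


class TestStandardization:
    def test_source_through_own_params_is_zscored(self):
        X = np.random.default_rng(0).normal(2.0, 3.0, size=(200, 5))
        params = d.StandardizationParams.fit(X)
        Z = params.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_passes_through(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        params = d.StandardizationParams.fit(X)
        assert params.scale[0] == 1.0
        np.testing.assert_allclose(params.transform(X)[:, 0], 0.0)


class TestPairwiseDistance:
    def test_three_four_five(self):
        assert d.pairwise_mean_distance(np.array([[0, 0], [3, 4]])) == pytest.approx(5.0)

    def test_duplicate_rows_enumerate_all_pairs(self):
        rows = np.array([[0, 0], [0, 0], [3, 4]])
        assert d.pairwise_mean_distance(rows) == pytest.approx(10 / 3)

    def test_single_row_is_undefined(self):
        assert d.pairwise_mean_distance(np.array([[1.0, 2.0]])) is None


class TestRouting:
    def test_leaf_sets_partition_targets(self, small_domain):
        tree = small_domain["forest"].trees[0]
        T = small_domain["targets"]
        routing = d.route_targets(tree, T)
        leaves = [n for n in tree.nodes() if n.is_leaf]
        leaf_idx = np.concatenate([routing[id(n)] for n in leaves])
        assert sorted(leaf_idx.tolist()) == list(range(T.shape[0]))
        for node in tree.internal_nodes():
            parent = set(routing[id(node)].tolist())
            left = set(routing[id(node.left)].tolist())
            right = set(routing[id(node.right)].tolist())
            assert left | right == parent and not (left & right)

    def test_empty_target_set_routes_nothing(self, small_domain):
        tree = small_domain["forest"].trees[0]
        routing = d.route_targets(tree, np.empty((0, 10)))
        assert all(idx.size == 0 for idx in routing.values())


def hand_tree(threshold=0.0, feature=0):
    mk = lambda dist: d.Node(None, None, None, None, np.asarray(dist, float), 5)
    return d.DecisionTree(
        root=d.Node(feature, threshold, mk([0.8, 0.1, 0.1]), mk([0.1, 0.1, 0.8]),
                    np.array([0.45, 0.1, 0.45]), 10)
    )


class TestPrune:
    def test_split_separating_clusters_is_kept(self):
        T = np.array([[-2.0, 0], [-2.1, 0], [2.0, 0], [2.1, 0]])
        pruned = d.prune_tree(hand_tree(), T)
        assert not pruned.root.is_leaf
        assert pruned.variant == "T_prune"

    def test_split_interleaving_one_cluster_is_snipped(self):
        # both children keep widely separated genes: D_i < D_a and D_i < D_b
        T = np.array([[-0.5, -10.0], [-0.4, 10.0], [0.4, -10.0], [0.5, 10.0]])
        d_i = mean_pair_dist(T)
        assert d_i < mean_pair_dist(T[:2]) and d_i < mean_pair_dist(T[2:])
        pruned = d.prune_tree(hand_tree(), T)
        assert pruned.root.is_leaf
        np.testing.assert_allclose(pruned.root.dist, [0.45, 0.1, 0.45])

    def test_no_targets_leaves_tree_unchanged(self, small_domain):
        tree = small_domain["forest"].trees[0]
        pruned = d.prune_tree(tree, np.empty((0, 10)))
        assert pruned.root.structurally_equal(tree.root)

    def test_matches_bruteforce_oracle(self):
        for tree, T in random_instances(60, seed=21):
            expected = brute_prune(tree.root, T, np.arange(T.shape[0]))
            assert d.prune_tree(tree, T).root.structurally_equal(expected)

    def test_prune_is_topological_contraction(self):
        for tree, T in random_instances(30, seed=22):
            pruned = d.prune_tree(tree, T)

            def contained(p, q):  # p: pruned node, q: original node
                if p.is_leaf:
                    return True
                return (
                    p.feature == q.feature and p.threshold == q.threshold
                    and contained(p.left, q.left) and contained(p.right, q.right)
                )

            assert contained(pruned.root, tree.root)


class TestShift:
    def test_moves_threshold_to_cluster_gap(self):
        T = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
        shifted = d.shift_thresholds(hand_tree(threshold=0.5), T)
        assert shifted.root.threshold == pytest.approx(5.5)
        assert shifted.variant == "T_shift"

    def test_tie_keeps_original_threshold(self):
        # all candidates yield the same partition -> tie broken toward t0
        T = np.array([[5.0, 0], [5.0, 0], [5.0, 1.0]])
        shifted = d.shift_thresholds(hand_tree(threshold=-3.0), T)
        assert shifted.root.threshold == pytest.approx(-3.0)

    def test_single_routed_gene_keeps_threshold(self):
        shifted = d.shift_thresholds(hand_tree(threshold=0.7), np.array([[2.0, 0.0]]))
        assert shifted.root.threshold == pytest.approx(0.7)

    def test_matches_exhaustive_grid_oracle(self):
        for tree, T in random_instances(60, seed=23):
            expected = brute_shift(tree.root, T, np.arange(T.shape[0]))
            assert d.shift_thresholds(tree, T).root.structurally_equal(expected)

    def test_topology_and_features_unchanged(self):
        for tree, T in random_instances(30, seed=24):
            shifted = d.shift_thresholds(tree, T)

            def same_shape(a, b):
                if a.is_leaf != b.is_leaf:
                    return False
                if a.is_leaf:
                    return bool(np.allclose(a.dist, b.dist))
                return a.feature == b.feature and same_shape(a.left, b.left) and same_shape(a.right, b.right)

            assert same_shape(shifted.root, tree.root)


class TestAssembly:
    def test_adapted_forest_doubles_tree_count(self, small_domain):
        adapted = d.build_rf_mouse(small_domain["forest"], small_domain["targets"])
        assert len(adapted.trees) == 2 * len(small_domain["forest"].trees)
        assert adapted.kind == "RF_mouse"
        variants = [t.variant for t in adapted.trees]
        assert variants.count("T_prune") == variants.count("T_shift") == 50

    def test_two_tree_toy_source(self, small_domain):
        toy = d.Forest(trees=small_domain["forest"].trees[:2], kind="RF")
        adapted = d.build_rf_mouse(toy, small_domain["targets"])
        assert [t.variant for t in adapted.trees] == ["T_prune", "T_prune", "T_shift", "T_shift"]

    def test_empty_target_matrix_refused(self, small_domain):
        with pytest.raises(InsufficientTargetError, match="insufficient target data"):
            d.build_rf_mouse(small_domain["forest"], np.empty((0, 10)))

    def test_adapted_probabilities_sum_to_one(self, small_domain):
        adapted = d.build_rf_mouse(small_domain["forest"], small_domain["targets"])
        X = np.random.default_rng(1).normal(size=(50, 10))
        np.testing.assert_allclose(d.predict_proba(adapted, X).sum(axis=1), 1.0, atol=1e-12)
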