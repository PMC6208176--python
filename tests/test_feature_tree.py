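"""Feature-tree construction, scoring (with an independent brute-force
oracle of the local kNN criterion) and Monte-Carlo search."""

import numpy as np
import pytest

from emofuse.feature_tree import (
    FeatureNode,
    FeatureTree,
    Leaf,
    LocalSubsetSelector,
    ScoreConfig,
    SplitNode,
    assign_locality,
    partition,
    score,
    search,
    single_leaf_tree,
    two_locality_subsets,
)
from emofuse.simulate import generate_local_feature_table


def brute_score(tree, X, y, k):
    """Independent reimplementation: route each sample recursively, then a
    double loop over same-locality pairs for the kNN fractions."""
    X = np.asarray(X, float)
    y = np.asarray(y)

    def route(x):
        node = tree.root
        feats = []
        while not isinstance(node, Leaf):
            if isinstance(node, FeatureNode):
                feats.append(node.feature)
                node = node.child
            else:
                node = node.left if x[node.feature] <= node.threshold else node.right
        return node.locality_id, tuple(feats)

    assignments = [route(x) for x in X]
    total = 0.0
    for i in range(len(X)):
        lid, feats = assignments[i]
        mates = [j for j in range(len(X)) if j != i and assignments[j][0] == lid]
        if not mates:
            continue
        cols = list(feats) if feats else list(range(X.shape[1]))
        dists = sorted(
            (np.linalg.norm(X[i, cols] - X[j, cols]), j) for j in mates
        )
        kk = min(k, len(mates))
        neighbours = [j for _, j in dists[:kk]]
        total += np.mean([y[j] == y[i] for j in neighbours])
    return total / len(X)


def random_tree(rng, n_features, depth=0, max_depth=3, used=frozenset()):
    choice = rng.random()
    if depth >= max_depth or choice < 0.3:
        return Leaf(locality_id=int(rng.integers(1_000_000)))
    if choice < 0.6 and len(used) < n_features:
        f = int(rng.choice([i for i in range(n_features) if i not in used]))
        return FeatureNode(
            feature=f,
            child=random_tree(rng, n_features, depth + 1, max_depth, used | {f}),
        )
    f = int(rng.integers(n_features))
    thr = float(rng.normal())
    return SplitNode(
        feature=f, threshold=thr,
        left=random_tree(rng, n_features, depth + 1, max_depth, used),
        right=random_tree(rng, n_features, depth + 1, max_depth, used),
    )


class TestTreeStructure:
    def test_repeated_feature_node_on_path_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            FeatureTree(
                root=FeatureNode(feature=2, child=FeatureNode(feature=2, child=Leaf(0)))
            )

    def test_serialization_roundtrip(self, rng):
        tree = FeatureTree(root=random_tree(rng, 6))
        clone = FeatureTree.from_dict(tree.to_dict())
        assert clone.to_dict() == tree.to_dict()


class TestAssignLocality:
    def test_single_leaf_everything_maps_there(self, rng):
        tree = single_leaf_tree()
        for x in rng.standard_normal((5, 3)):
            loc = assign_locality(tree, x)
            assert loc.locality_id == 0
            assert loc.feature_subset == ()

    def test_feature_node_above_split_shared_by_both_localities(self):
        """A feature node above a split is inherited by both child localities
        (the compound-locality sharing the tree encodes)."""
        tree = FeatureTree(
            root=FeatureNode(
                feature=4,
                child=SplitNode(
                    feature=1, threshold=0.0,
                    left=FeatureNode(feature=2, child=Leaf(0)),
                    right=Leaf(1),
                ),
            )
        )
        left = assign_locality(tree, np.array([0.0, -1.0, 0.0, 0.0, 0.0]))
        right = assign_locality(tree, np.array([0.0, +1.0, 0.0, 0.0, 0.0]))
        assert left.locality_id == 0 and left.feature_subset == (4, 2)
        assert right.locality_id == 1 and right.feature_subset == (4,)

    def test_split_routes_left_on_ties(self):
        tree = FeatureTree(
            root=SplitNode(feature=0, threshold=1.0, left=Leaf(0), right=Leaf(1))
        )
        assert assign_locality(tree, np.array([1.0])).locality_id == 0

    def test_partition_matches_per_sample_routing(self, rng):
        tree = FeatureTree(root=random_tree(rng, 5))
        X = rng.standard_normal((100, 5))
        parts = partition(tree, X)
        # disjoint and exhaustive
        all_idx = np.sort(np.concatenate([idx for idx, _ in parts.values()]))
        np.testing.assert_array_equal(all_idx, np.arange(100))
        for lid, (idx, feats) in parts.items():
            for i in idx:
                loc = assign_locality(tree, X[i])
                assert loc.locality_id == lid
                assert loc.feature_subset == feats


class TestScore:
    def test_uniform_labels_score_one(self, rng):
        X = rng.standard_normal((20, 3))
        assert score(single_leaf_tree(), X, np.zeros(20), ScoreConfig(k=3)) == 1.0

    def test_two_conflicting_samples_score_zero(self):
        X = np.array([[0.0], [1.0]])
        assert score(single_leaf_tree(), X, [0, 1], ScoreConfig(k=1)) == 0.0

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            score(single_leaf_tree(), np.empty((0, 2)), [], ScoreConfig())

    def test_score_within_unit_interval(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            tree = FeatureTree(root=random_tree(r, 4))
            X = r.standard_normal((30, 4))
            y = r.integers(0, 2, 30)
            s = score(tree, X, y, ScoreConfig(k=3))
            assert 0.0 <= s <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        """The optimized score equals the explicit O(n^2) double loop."""
        r = np.random.default_rng(seed)
        tree = FeatureTree(root=random_tree(r, 4))
        X = r.standard_normal((20, 4))
        y = r.integers(0, 2, 20)
        cfg = ScoreConfig(k=3)
        assert score(tree, X, y, cfg) == pytest.approx(
            brute_score(tree, X, y, 3), abs=1e-12
        )


class TestSearch:
    def _planted(self, seed):
        tab = generate_local_feature_table(300, 12, ({0, 1}, {2, 3}, 9), seed=seed)
        X = tab[[f"f{i}" for i in range(12)]].to_numpy()
        return X, tab["label"].to_numpy()

    def test_budget_one_terminates(self):
        X, y = self._planted(0)
        tree = search(X, y, ScoreConfig(k=3), budget=1, max_depth=3, seed=0)
        assert tree.n_leaves() >= 1

    def test_never_below_single_leaf(self):
        """Search score >= single-leaf score on random tables."""
        cfg = ScoreConfig(k=3)
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 5))
            y = r.integers(0, 2, 40)
            tree = search(X, y, cfg, budget=30, max_depth=3, seed=seed)
            assert score(tree, X, y, cfg) >= score(single_leaf_tree(), X, y, cfg) - 1e-12

    def test_seeded_determinism(self):
        X, y = self._planted(1)
        t1 = search(X, y, ScoreConfig(k=3), budget=50, seed=42)
        t2 = search(X, y, ScoreConfig(k=3), budget=50, seed=42)
        assert t1.to_dict() == t2.to_dict()

    def test_two_leaf_search_beats_single_leaf_on_planted(self):
        cfg = ScoreConfig(k=5)
        X, y = self._planted(2)
        tree = search(X, y, cfg, budget=200, max_depth=4, seed=0,
                      exactly_two_leaves=True)
        assert tree.n_leaves() == 2
        assert score(tree, X, y, cfg) > score(single_leaf_tree(), X, y, cfg)


class TestTwoLocalitySubsets:
    def test_subset_sizes(self, rng):
        X = rng.standard_normal((40, 15))
        ya = rng.integers(0, 2, 40)
        yv = rng.integers(0, 2, 40)
        a, v = two_locality_subsets(X, ya, yv, budget=20, n_keep=10, seed=0)
        assert len(a) == 10 and len(v) == 10

    def test_n_keep_at_least_feature_count_returns_all(self, rng):
        X = rng.standard_normal((30, 6))
        ya = rng.integers(0, 2, 30)
        with pytest.warns(UserWarning, match="available"):
            a, v = two_locality_subsets(X, ya, ya, budget=10, n_keep=10, seed=0)
        assert a == list(range(6)) and v == list(range(6))

    def test_planted_recovery(self):
        """Arousal/valence subsets recover their planted feature sets."""
        from emofuse.simulate import generate_quadrant_feature_table

        hits = 0
        for seed in range(5):
            tab = generate_quadrant_feature_table(150, 20, {0, 1}, {2, 3}, seed=seed)
            X = tab[[f"f{i}" for i in range(20)]].to_numpy()
            a, v = two_locality_subsets(
                X,
                (tab["arousal"] > 5).astype(int),
                (tab["valence"] > 5).astype(int),
                budget=200, n_keep=5, seed=seed,
            )
            hits += bool(set(a) & {0, 1})
        assert hits >= 4


class TestSelectorEstimator:
    def test_sklearn_interface(self, rng):
        from emofuse.simulate import generate_quadrant_feature_table

        tab = generate_quadrant_feature_table(80, 12, {0}, {1}, seed=0)
        X = tab[[f"f{i}" for i in range(12)]].to_numpy()
        y = tab[["arousal", "valence"]].to_numpy()
        sel = LocalSubsetSelector(budget=30, n_keep=4, random_state=0).fit(X, y)
        assert len(sel.arousal_subset_) == 4
        Xt = sel.transform(X)
        assert Xt.shape[1] == sel.support_.sum()
        assert sel.get_params()["n_keep"] == 4
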