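"""Local subset feature selection via feature trees.

A *feature tree* is a univariate binary decision tree with a third node
kind: a single-child *feature node* that attributes its feature to every
locality below it.  Leaves are *localities*: disjoint regions of the sample
space, each owning the set of features collected on its root-to-leaf path.

A tree is scored by local k-nearest-neighbour label agreement: for every
training sample, the fraction of its k nearest neighbours *within its own
locality* (distances measured over the locality's feature subset; an empty
subset falls back to all features) that share its label, averaged over the
training set.  This is 1/(K|S|) * sum_x sum_{y in kNN(x)} [label(y)=label(x)]
whenever every locality can supply k neighbours; smaller localities truncate
k and contribute the per-sample fraction (a singleton contributes 0).

Tree construction is a sequential decision problem: at each open node the
available actions are "make feature node f_i" (for any feature not already a
feature node on the path), "make splitting node s_i" (threshold at the
median of the node's samples), or "terminate" (leaf).  A Monte-Carlo search
with an epsilon-greedy bandit over per-state action values grows ``budget``
complete trees and returns the best one encountered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "Leaf",
    "FeatureNode",
    "SplitNode",
    "FeatureTree",
    "ScoreConfig",
    "assign_locality",
    "score",
    "search",
    "two_locality_subsets",
    "LocalSubsetSelector",
]


@dataclass
class Leaf:
    locality_id: int


@dataclass
class FeatureNode:
    feature: int
    child: "Node"


@dataclass
class SplitNode:
    feature: int
    threshold: float
    left: "Node"
    right: "Node"


Node = Union[Leaf, FeatureNode, SplitNode]


@dataclass
class FeatureTree:
    """Wrapper around the root node with routing and serialization helpers."""

    root: Node

    def __post_init__(self) -> None:
        self._check_paths(self.root, frozenset())

    @staticmethod
    def _check_paths(node: Node, used: frozenset) -> None:
        if isinstance(node, Leaf):
            return
        if isinstance(node, FeatureNode):
            if node.feature in used:
                raise ValueError(
                    f"feature {node.feature} repeated as feature node on a path"
                )
            FeatureTree._check_paths(node.child, used | {node.feature})
            return
        FeatureTree._check_paths(node.left, used)
        FeatureTree._check_paths(node.right, used)

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if isinstance(node, Leaf):
                return 1
            if isinstance(node, FeatureNode):
                return count(node.child)
            return count(node.left) + count(node.right)

        return count(self.root)

    def to_dict(self) -> dict:
        def conv(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {"kind": "leaf", "locality_id": node.locality_id}
            if isinstance(node, FeatureNode):
                return {
                    "kind": "feature",
                    "feature_index": node.feature,
                    "child": conv(node.child),
                }
            return {
                "kind": "split",
                "feature_index": node.feature,
                "threshold": node.threshold,
                "left": conv(node.left),
                "right": conv(node.right),
            }

        return conv(self.root)

    @staticmethod
    def from_dict(d: dict) -> "FeatureTree":
        def conv(d: dict) -> Node:
            if d["kind"] == "leaf":
                return Leaf(locality_id=d["locality_id"])
            if d["kind"] == "feature":
                return FeatureNode(feature=d["feature_index"], child=conv(d["child"]))
            return SplitNode(
                feature=d["feature_index"],
                threshold=d["threshold"],
                left=conv(d["left"]),
                right=conv(d["right"]),
            )

        return FeatureTree(root=conv(d))


def single_leaf_tree() -> FeatureTree:
    return FeatureTree(root=Leaf(locality_id=0))


@dataclass
class ScoreConfig:
    """k of the local kNN criterion; distances are Euclidean over the
    locality's feature subset."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class Locality:
    locality_id: int
    feature_subset: tuple[int, ...]


def assign_locality(tree: FeatureTree, x: Sequence[float]) -> Locality:
    """Route a sample to its leaf; splits go left iff value <= threshold."""
    x = np.asarray(x, dtype=float)
    node = tree.root
    feats: list[int] = []
    while not isinstance(node, Leaf):
        if isinstance(node, FeatureNode):
            feats.append(node.feature)
            node = node.child
        else:
            node = node.left if x[node.feature] <= node.threshold else node.right
    return Locality(locality_id=node.locality_id, feature_subset=tuple(feats))


def partition(
    tree: FeatureTree, X: np.ndarray
) -> dict[int, tuple[np.ndarray, tuple[int, ...]]]:
    """Locality id -> (sample indices, feature subset). Vectorized routing."""
    X = np.asarray(X, dtype=float)
    out: dict[int, tuple[np.ndarray, tuple[int, ...]]] = {}

    def walk(node: Node, idx: np.ndarray, feats: tuple[int, ...]) -> None:
        if isinstance(node, Leaf):
            out[node.locality_id] = (idx, feats)
            return
        if isinstance(node, FeatureNode):
            walk(node.child, idx, feats + (node.feature,))
            return
        go_left = X[idx, node.feature] <= node.threshold
        walk(node.left, idx[go_left], feats)
        walk(node.right, idx[~go_left], feats)

    walk(tree.root, np.arange(len(X)), ())
    return out


def score(
    tree: FeatureTree,
    X: np.ndarray,
    y: Sequence,
    cfg: ScoreConfig | None = None,
) -> float:
    """Local kNN label-agreement score of a feature tree, in [0, 1]."""
    cfg = cfg or ScoreConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    fractions = np.zeros(len(X))
    for idx, feats in partition(tree, X).values():
        if len(idx) == 0:
            continue
        if len(idx) == 1:
            fractions[idx[0]] = 0.0
            continue
        sub = X[np.ix_(idx, list(feats))] if feats else X[idx]
        D = cdist(sub, sub)
        np.fill_diagonal(D, np.inf)
        k = min(cfg.k, len(idx) - 1)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        same = y[idx][order] == y[idx][:, None]
        fractions[idx] = same.mean(axis=1)
    return float(fractions.mean())


# ---------------------------------------------------------------------------
# Monte-Carlo tree search over the action space {f_1..f_F, s_1..s_F, T}
# ---------------------------------------------------------------------------


@dataclass
class _SearchStats:
    counts: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def mean(self, key) -> float:
        c = self.counts.get(key, 0)
        return self.values.get(key, 0.0) / c if c else np.inf  # optimistic init

    def update(self, key, value: float) -> None:
        self.counts[key] = self.counts.get(key, 0) + 1
        self.values[key] = self.values.get(key, 0.0) + value


@dataclass
class RolloutRecord:
    tree: FeatureTree
    score: float
    features_used: frozenset


def _valid_actions(
    used_features: tuple[int, ...],
    n_features: int,
    depth: int,
    max_depth: int,
    split_done: bool,
    exactly_two_leaves: bool,
) -> list[tuple[str, int]]:
    """Action list at an open node.  Actions are ('T', -1), ('f', i), ('s', i)."""
    if depth >= max_depth:
        if exactly_two_leaves and not split_done:
            # cannot terminate without the split: allow splits only
            return [("s", i) for i in range(n_features)]
        return [("T", -1)]
    actions: list[tuple[str, int]] = []
    if not (exactly_two_leaves and not split_done):
        actions.append(("T", -1))
    used = set(used_features)
    actions.extend(("f", i) for i in range(n_features) if i not in used)
    if not (exactly_two_leaves and split_done):
        actions.extend(("s", i) for i in range(n_features))
    return actions


def _median_threshold(values: np.ndarray) -> float:
    """Midpoint between the two middle sorted values (balanced split)."""
    v = np.sort(values)
    if len(v) < 2:
        return float(v[0]) if len(v) else 0.0
    mid = len(v) // 2
    return float(0.5 * (v[mid - 1] + v[mid]))


def search(
    X: np.ndarray,
    y: Sequence,
    cfg: ScoreConfig | None = None,
    budget: int = 500,
    max_depth: int = 4,
    seed: int = 0,
    epsilon: float = 0.2,
    exactly_two_leaves: bool = False,
    return_records: bool = False,
):
    """Monte-Carlo feature-tree search with an epsilon-greedy action bandit.

    Grows ``budget`` complete trees; at each open node the action (feature
    node, splitting node at the node-median threshold, or terminate) is
    chosen epsilon-greedily from per-state Monte-Carlo value estimates
    (states are the root-to-node action sequences).  Returns the
    highest-scoring tree encountered; deterministic given the seed.
    """
    cfg = cfg or ScoreConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    n_features = X.shape[1]
    rng = np.random.default_rng(seed)
    stats = _SearchStats()

    def rollout() -> tuple[FeatureTree, frozenset, float]:
        next_leaf = [0]
        used_global: set[int] = set()
        # tree-global split flag for the exactly-two-leaves constraint
        state = {"split_done": False}

        def build(idx: np.ndarray, path_feats: tuple[int, ...], state_key: tuple,
                  depth: int, trajectory: list) -> Node:
            actions = _valid_actions(
                path_feats, n_features, depth, max_depth,
                state["split_done"], exactly_two_leaves,
            )
            if not actions:  # pragma: no cover - safety
                actions = [("T", -1)]
            if rng.random() < epsilon:
                a = actions[rng.integers(len(actions))]
            else:
                means = np.array([stats.mean((state_key, act)) for act in actions])
                best = np.flatnonzero(means == means.max())
                a = actions[best[0]]
            trajectory.append((state_key, a))
            kind, feat = a
            if kind == "T":
                leaf = Leaf(locality_id=next_leaf[0])
                next_leaf[0] += 1
                return leaf
            if kind == "f":
                used_global.add(feat)
                child = build(
                    idx, path_feats + (feat,), state_key + (a,), depth + 1, trajectory
                )
                return FeatureNode(feature=feat, child=child)
            # split node
            state["split_done"] = True
            used_global.add(feat)
            thr = _median_threshold(X[idx, feat]) if len(idx) else 0.0
            go_left = X[idx, feat] <= thr
            left = build(idx[go_left], path_feats, state_key + (a, "L"), depth + 1,
                         trajectory)
            right = build(idx[~go_left], path_feats, state_key + (a, "R"), depth + 1,
                          trajectory)
            return SplitNode(feature=feat, threshold=thr, left=left, right=right)

        trajectory: list = []
        root = build(np.arange(len(X)), (), (), 0, trajectory)
        tree = FeatureTree(root=root)
        s = score(tree, X, y, cfg)
        for key in trajectory:
            stats.update(key, s)
        return tree, frozenset(used_global), s

    best_tree, best_score = None, -np.inf
    if not exactly_two_leaves:
        # the degenerate tree is always a candidate, so the search can
        # never return something worse than no partitioning at all
        best_tree = single_leaf_tree()
        best_score = score(best_tree, X, y, cfg)
    records: list[RolloutRecord] = []
    for _ in range(budget):
        tree, used, s = rollout()
        if return_records:
            records.append(RolloutRecord(tree=tree, score=s, features_used=used))
        if s > best_score:
            best_tree, best_score = tree, s

    if best_tree is None:  # pragma: no cover - budget >= 1 always yields a tree
        warnings.warn("search budget exhausted without a valid tree")
        best_tree = single_leaf_tree()
    if return_records:
        return best_tree, records
    return best_tree


def rank_features(
    records: Sequence[RolloutRecord], baseline: float, n_features: int
) -> np.ndarray:
    """Rank features by rollout selection frequency weighted by score gain.

    A feature's weight accumulates, over every rollout tree that used it,
    the tree's score relative to the reference level (the larger of the
    single-leaf baseline and the mean rollout score).  Features that keep
    appearing in above-reference trees rank high; features that only occur
    in weak trees accumulate negative weight.
    """
    if not records:
        return np.arange(n_features)
    reference = max(baseline, float(np.mean([rec.score for rec in records])))
    weight = np.zeros(n_features)
    for rec in records:
        gain = rec.score - reference
        for f in rec.features_used:
            weight[f] += gain
    # stable ranking: weight descending, index ascending
    return np.lexsort((np.arange(n_features), -weight))


def two_locality_subsets(
    X: np.ndarray,
    y_arousal: Sequence,
    y_valence: Sequence,
    cfg: ScoreConfig | None = None,
    budget: int = 500,
    max_depth: int = 4,
    n_keep: int = 10,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Arousal and valence feature subsets from two independent searches.

    Each search is constrained to trees with exactly two leaves (one split
    plus feature nodes) and scored against one binarized label axis; the
    returned subsets hold the ``n_keep`` highest-ranked features (rollout
    selection frequency weighted by score gain over the single-leaf tree).
    """
    cfg = cfg or ScoreConfig()
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if n_keep > n_features:
        warnings.warn(
            f"n_keep={n_keep} exceeds the {n_features} available features; "
            "returning all features"
        )
    keep = min(n_keep, n_features)
    subsets = []
    for axis_idx, y in enumerate((y_arousal, y_valence)):
        baseline = score(single_leaf_tree(), X, y, cfg)
        _, records = search(
            X, y, cfg=cfg, budget=budget, max_depth=max_depth,
            seed=(int(seed) * 2 + axis_idx) % (2**31), epsilon=0.2,
            exactly_two_leaves=True, return_records=True,
        )
        order = rank_features(records, baseline, n_features)
        subsets.append(sorted(int(f) for f in order[:keep]))
    return subsets[0], subsets[1]


class LocalSubsetSelector(BaseEstimator):
    """Selects arousal- and valence-locality feature subsets (sklearn style).

    ``fit(X, y)`` expects ``y`` of shape (n_samples, 2): binarized (or raw
    1-9) arousal and valence labels.  Fitted attributes: ``arousal_subset_``
    and ``valence_subset_`` (column indices), ``support_`` (boolean union
    mask usable for transform).
    """

    def __init__(
        self,
        k: int = 5,
        budget: int = 500,
        max_depth: int = 4,
        n_keep: int = 10,
        random_state: int = 0,
    ):
        self.k = k
        self.budget = budget
        self.max_depth = max_depth
        self.n_keep = n_keep
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n_samples, 2): arousal and valence labels")
        y = y.astype(float)
        if not np.isin(np.unique(y), (0.0, 1.0)).all():
            y = (y > 5.0).astype(int)  # raw 1-9 ratings: binarize at the midpoint
        cfg = ScoreConfig(k=self.k)
        self.arousal_subset_, self.valence_subset_ = two_locality_subsets(
            X, y[:, 0], y[:, 1], cfg=cfg, budget=self.budget,
            max_depth=self.max_depth, n_keep=self.n_keep, seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.arousal_subset_] = True
        self.support_[self.valence_subset_] = True
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]
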