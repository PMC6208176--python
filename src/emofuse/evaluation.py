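"""Confusion/confidence matrices, CCR and leakage-free cross-validation.

The confusion matrix follows the convention rows = decision, columns =
target; the confidence matrix column-normalizes it to percentages, and the
correct classification rate (CCR) is the trace over the grand total.

``cross_validate_pipeline`` runs the full chain under stratified k-fold CV
with every data-dependent choice (class activity maps, channel threshold
intersection, feature-subset search, prototypes, MLP weights) refit inside
each training fold.  Per-epoch computations (SOBI activity vectors, the
per-channel feature values) depend on one epoch only, so they are computed
once up front without leaking information across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from . import bss, channels as channels_mod, features as features_mod
from .dst import DempsterShaferClassifier
from .feature_tree import ScoreConfig, two_locality_subsets
from .quadrants import QUARTERS, binarize_arousal, binarize_valence
from .simulate import EEGEpoch

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "confidence",
    "ccr",
    "CVPlan",
    "make_cv_plan",
    "PipelineSettings",
    "CVResult",
    "cross_validate_pipeline",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = decision, columns = target, class order Q1..Q4."""

    counts: np.ndarray
    labels: tuple[str, ...] = QUARTERS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} count matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="decision"),
            columns=pd.Index(self.labels, name="target"),
        )


def confusion(
    decisions: Sequence, targets: Sequence, labels: Sequence[str] = QUARTERS
) -> ConfusionMatrix:
    """Tally decisions against targets: counts[d, t]."""
    counts = _sk_confusion(targets, decisions, labels=list(labels)).T
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def confidence(cm: ConfusionMatrix) -> np.ndarray:
    """Column-normalized percentages: 100 * counts[d, t] / column_total[t]."""
    counts = cm.counts.astype(float)
    col = counts.sum(axis=0, keepdims=True)
    col[col == 0] = np.nan
    return 100.0 * counts / col


def ccr(cm: ConfusionMatrix) -> float:
    """Correct classification rate: trace / grand total."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


@dataclass
class CVPlan:
    """Fold assignment per sample; folds partition the data, sizes differ <= 1
    within each stratum."""

    n_folds: int
    assignments: np.ndarray
    seed: int


def make_cv_plan(labels: Sequence, n_folds: int = 10, seed: int = 0) -> CVPlan:
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            f"a class has only {counts.min()} samples for {n_folds} folds; "
            "stratification will be uneven",
            stacklevel=2,
        )
        n_folds = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=seed)


@dataclass
class PipelineSettings:
    """All tunables of the end-to-end chain."""

    channel_threshold: float = 0.4
    threshold_grid: tuple = channels_mod.DEFAULT_THRESHOLD_GRID
    feature_params: features_mod.FeatureParams = field(
        default_factory=features_mod.FeatureParams
    )
    knn_k: int = 5
    search_budget: int = 300
    search_max_depth: int = 4
    n_keep: int = 10
    membership_threshold: float = 0.4
    hidden_layer_sizes: tuple = (20,)
    mlp_max_iter: int = 500
    n_folds: int = 10
    seed: int = 0


@dataclass
class CVResult:
    fold_matrices: list
    pooled: ConfusionMatrix
    pooled_ccr: float
    fused_accuracy: float
    source_accuracies: tuple[float, float]
    selected_channels: list
    arousal_subsets: list
    valence_subsets: list

    def report(self) -> str:
        """Markdown report mirroring the count-over-percentage table layout."""
        conf = confidence(self.pooled)
        lines = ["| Decision \\ Target | " + " | ".join(self.pooled.labels) + " |"]
        lines.append("|---" * (len(self.pooled.labels) + 1) + "|")
        for i, lab in enumerate(self.pooled.labels):
            cells = [
                f"{self.pooled.counts[i, j]}<br>{conf[i, j]:.2f}%"
                for j in range(len(self.pooled.labels))
            ]
            lines.append(f"| {lab} | " + " | ".join(cells) + " |")
        lines.append("")
        lines.append(f"Pooled CCR: {self.pooled_ccr:.4f}")
        lines.append(f"Fused accuracy: {self.fused_accuracy:.4f}")
        lines.append(
            "Single-source accuracies (arousal, valence subsets): "
            f"{self.source_accuracies[0]:.4f}, {self.source_accuracies[1]:.4f}"
        )
        return "\n".join(lines)


def _per_epoch_activity(epochs: Sequence[EEGEpoch]) -> list[np.ndarray]:
    return [bss.component_activity(bss.sobi(ep.data)) for ep in epochs]


def _select_fold_channels(
    activity: Sequence[np.ndarray],
    quarters: Sequence[str],
    train_idx: np.ndarray,
    settings: PipelineSettings,
    channel_labels: Sequence[str],
) -> channels_mod.ChannelSet:
    maps = bss.activity_maps_by_class(
        [activity[i] for i in train_idx], [quarters[i] for i in train_idx]
    )
    grid = sorted({settings.channel_threshold, *settings.threshold_grid})
    # walk down from the configured threshold until the intersection is nonempty
    for thr in [settings.channel_threshold] + [
        t for t in reversed(grid) if t < settings.channel_threshold
    ]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sets = [
                    channels_mod.select_emotional_channels(maps[q], thr, channel_labels)
                    for q in QUARTERS
                ]
                return channels_mod.intersect_channels(sets)
        except channels_mod.EmptyIntersectionError:
            continue
    raise channels_mod.EmptyIntersectionError(
        "no threshold in the grid yields a nonempty channel intersection"
    )


def cross_validate_pipeline(
    epochs: Sequence[EEGEpoch],
    settings: PipelineSettings | None = None,
) -> CVResult:
    """Stratified k-fold CV of the full chain; pooled counts reported."""
    settings = settings or PipelineSettings()
    quarters = [ep.quarter for ep in epochs]
    channel_labels = epochs[0].channel_labels

    activity = _per_epoch_activity(epochs)
    all_channels = channels_mod.ChannelSet(
        indices=tuple(range(epochs[0].n_channels)),
        labels=tuple(channel_labels),
        class_label="all",
    )
    table = features_mod.extract_features(epochs, all_channels, settings.feature_params)
    feature_cols = [c for c in table.columns if c not in ("quarter", "arousal", "valence")]
    X_all = table[feature_cols].to_numpy()
    y = np.asarray(quarters)
    y_arousal = np.array([binarize_arousal(ep.arousal) for ep in epochs])
    y_valence = np.array([binarize_valence(ep.valence) for ep in epochs])

    plan = make_cv_plan(y, n_folds=settings.n_folds, seed=settings.seed)
    fold_matrices, selected_sets = [], []
    arousal_subsets, valence_subsets = [], []
    decisions = np.empty(len(epochs), dtype=object)
    src_decisions = [np.empty(len(epochs), dtype=object) for _ in range(2)]

    for fold in range(plan.n_folds):
        test_idx = np.flatnonzero(plan.assignments == fold)
        train_idx = np.flatnonzero(plan.assignments != fold)

        chan_set = _select_fold_channels(
            activity, quarters, train_idx, settings, channel_labels
        )
        selected_sets.append(chan_set)
        cols = [
            i
            for i, c in enumerate(feature_cols)
            if c.rsplit("_", 1)[0] in chan_set.labels
        ]
        X = X_all[:, cols]

        a_sub, v_sub = two_locality_subsets(
            X[train_idx],
            y_arousal[train_idx],
            y_valence[train_idx],
            cfg=ScoreConfig(k=settings.knn_k),
            budget=settings.search_budget,
            max_depth=settings.search_max_depth,
            n_keep=settings.n_keep,
            seed=settings.seed + fold,
        )
        arousal_subsets.append([feature_cols[cols[i]] for i in a_sub])
        valence_subsets.append([feature_cols[cols[i]] for i in v_sub])

        clf = DempsterShaferClassifier(
            feature_subsets=[a_sub, v_sub],
            membership_threshold=settings.membership_threshold,
            hidden_layer_sizes=settings.hidden_layer_sizes,
            max_iter=settings.mlp_max_iter,
            random_state=settings.seed + fold,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[train_idx], y[train_idx])
        decisions[test_idx] = clf.predict(X[test_idx])
        for s, preds in enumerate(clf.source_predictions(X[test_idx])):
            src_decisions[s][test_idx] = preds
        fold_matrices.append(
            confusion(decisions[test_idx], y[test_idx])
        )

    pooled = ConfusionMatrix(
        counts=np.sum([cm.counts for cm in fold_matrices], axis=0)
    )
    fused_acc = float(np.mean(decisions == y))
    src_accs = tuple(float(np.mean(sd == y)) for sd in src_decisions)
    return CVResult(
        fold_matrices=fold_matrices,
        pooled=pooled,
        pooled_ccr=ccr(pooled),
        fused_accuracy=fused_acc,
        source_accuracies=src_accs,  # type: ignore[arg-type]
        selected_channels=selected_sets,
        arousal_subsets=arousal_subsets,
        valence_subsets=valence_subsets,
    )
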