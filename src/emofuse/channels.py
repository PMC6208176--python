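"""Thresholding activity maps into "emotional channels" and intersecting them.

A channel is *emotional* for a class when the absolute value of its
normalized activity exceeds a threshold (both strongly active and strongly
deactivated regions are informative).  Only channels emotional in **all
four** quadrants survive, so downstream feature extraction runs on a small
class-independent montage.  The threshold itself has no principled value; it
is tuned by trial and error against downstream classification performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .bss import ActivityMap
from .quadrants import QUARTERS

__all__ = [
    "ChannelSet",
    "select_emotional_channels",
    "intersect_channels",
    "tune_threshold",
    "EmptyIntersectionError",
]


class EmptyIntersectionError(ValueError):
    """No channel is emotional in all four classes; decrease the threshold."""


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel indices (and names) selected for one class."""

    indices: tuple[int, ...]
    labels: tuple[str, ...]
    class_label: str

    def __post_init__(self) -> None:
        if list(self.indices) != sorted(set(self.indices)):
            raise ValueError("channel indices must be strictly increasing")
        if self.labels and len(self.labels) != len(self.indices):
            raise ValueError("labels must match indices")

    def __len__(self) -> int:
        return len(self.indices)


def select_emotional_channels(
    activity_map: ActivityMap,
    threshold: float,
    channel_labels: Sequence[str] | None = None,
) -> ChannelSet:
    """Channels whose |normalized activity| strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    values = np.asarray(activity_map.values, dtype=float)
    indices = tuple(int(i) for i in np.flatnonzero(np.abs(values) > threshold))
    if not indices:
        warnings.warn(
            f"threshold {threshold} exceeds the peak |activity| for class "
            f"{activity_map.class_label}: empty channel set",
            stacklevel=2,
        )
    if channel_labels is None:
        labels = tuple(f"ch{i}" for i in indices)
    else:
        labels = tuple(channel_labels[i] for i in indices)
    return ChannelSet(indices=indices, labels=labels, class_label=activity_map.class_label)


def intersect_channels(per_class: Sequence[ChannelSet]) -> ChannelSet:
    """Channels common to every per-class set (class_label="intersection")."""
    if not per_class:
        raise ValueError("need at least one channel set")
    common = set(per_class[0].indices)
    label_of = dict(zip(per_class[0].indices, per_class[0].labels))
    for cs in per_class[1:]:
        common &= set(cs.indices)
        label_of.update(dict(zip(cs.indices, cs.labels)))
    if not common:
        raise EmptyIntersectionError(
            "no common emotional channels across classes; decrease the threshold"
        )
    indices = tuple(sorted(common))
    return ChannelSet(
        indices=indices,
        labels=tuple(label_of[i] for i in indices),
        class_label="intersection",
    )


def intersect_label_sets(per_class_labels: Sequence[Sequence[str]]) -> set[str]:
    """Set intersection of per-class electrode-name lists."""
    if not per_class_labels:
        raise ValueError("need at least one electrode list")
    common = set(per_class_labels[0])
    for labels in per_class_labels[1:]:
        common &= set(labels)
    return common


DEFAULT_THRESHOLD_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


def tune_threshold(
    maps: Mapping[str, ActivityMap],
    candidate_thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    downstream_scorer: Callable[[ChannelSet], float] | None = None,
    channel_labels: Sequence[str] | None = None,
) -> float:
    """Pick the candidate threshold maximizing the downstream score.

    The scorer maps the cross-class intersection ChannelSet to a score (e.g.
    a cross-validated accuracy).  Candidates with an empty intersection are
    skipped; ties go to the smallest threshold (more channels retained).
    """
    candidates = sorted(set(float(t) for t in candidate_thresholds))
    if not candidates:
        raise ValueError("need at least one candidate threshold")
    if downstream_scorer is None:
        downstream_scorer = len  # default: retain as many channels as possible
    class_order = [q for q in QUARTERS if q in maps] or sorted(maps)
    best_t, best_score = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in candidates:
            try:
                sets = [
                    select_emotional_channels(maps[q], t, channel_labels)
                    for q in class_order
                ]
                common = intersect_channels(sets)
            except (EmptyIntersectionError, ValueError):
                continue
            score = float(downstream_scorer(common))
            if score > best_score:  # strict: ties keep the smaller threshold
                best_t, best_score = t, score
    if best_t is None:
        raise EmptyIntersectionError(
            "every candidate threshold yields an empty intersection"
        )
    return best_t
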