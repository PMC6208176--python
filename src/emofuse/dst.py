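"""Modified Dempster-Shafer fusion of two MLP classifiers.

The frame of discernment is the four arousal-valence quadrants
phi = {Q1, Q2, Q3, Q4}; belief mass is assigned over its nonempty subsets.
Two independent MLPs, trained on the arousal- and valence-locality feature
subsets, produce per-class posterior scores; each score vector becomes a
singleton mass function through the softmax operator, the two mass
functions are combined by Dempster's rule (with conflict renormalization),
and the decision is the singleton with maximum belief (for singletons,
Bel({q}) = m({q})).

Training uses the distance-to-prototype relabeling of the evidential
framework: each training sample receives inverse-distance memberships to
the class prototypes; thresholding the memberships yields a target
*hypothesis* (possibly a set of classes), which the base learner sees as a
target distribution uniform over its member classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "MassFunction",
    "vacuous_mass",
    "softmax_mass",
    "dempster_combine",
    "decide",
    "class_prototypes",
    "relabel",
    "RelabeledSample",
    "DempsterShaferClassifier",
    "TotalConflictError",
]

_TOL = 1e-9


class TotalConflictError(ValueError):
    """Dempster combination undefined: the sources are in total conflict (K=1)."""


@dataclass(frozen=True)
class MassFunction:
    """Basic belief assignment over subsets of a frame of n classes.

    Hypotheses are frozensets of class indices.  Validity: m(empty) = 0,
    all masses >= 0, and the masses sum to 1 (within 1e-9).
    """

    masses: Mapping[frozenset, float]
    n_classes: int

    def __post_init__(self) -> None:
        total = 0.0
        for hyp, m in self.masses.items():
            if len(hyp) == 0 and m != 0.0:
                raise ValueError("mass on the empty set must be 0")
            if m < -_TOL:
                raise ValueError(f"negative mass {m} on {set(hyp)}")
            if any(not 0 <= i < self.n_classes for i in hyp):
                raise ValueError("hypothesis outside the frame")
            total += m
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"masses sum to {total}, expected 1")

    def mass(self, hypothesis: frozenset | set | Sequence[int]) -> float:
        return float(self.masses.get(frozenset(hypothesis), 0.0))

    def belief(self, hypothesis: frozenset | set | Sequence[int]) -> float:
        """Bel(S) = sum of masses of all nonempty subsets of S."""
        S = frozenset(hypothesis)
        return float(
            sum(m for hyp, m in self.masses.items() if hyp and hyp <= S)
        )

    def focal_elements(self) -> list[frozenset]:
        return [h for h, m in self.masses.items() if m > 0]


def vacuous_mass(n_classes: int) -> MassFunction:
    """Total ignorance: all mass on the full frame."""
    return MassFunction({frozenset(range(n_classes)): 1.0}, n_classes)


def softmax_mass(R: Sequence[float]) -> MassFunction:
    """Posterior scores -> singleton masses via the softmax operator.

    m({s_j}) = exp(R_j) / sum_c exp(R_c); shift-invariant and overflow-safe.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 1 or not np.all(np.isfinite(R)):
        raise ValueError("posterior scores must be a finite vector")
    p = _softmax(R)
    return MassFunction(
        {frozenset({j}): float(pj) for j, pj in enumerate(p)}, len(R)
    )


def dempster_combine(m1: MassFunction, m2: MassFunction) -> tuple[MassFunction, float]:
    """Dempster's rule of combination.

    m(S) = sum_{S1 ^ S2 = S} m1(S1) m2(S2) / (1 - K), with the conflict
    K = sum_{S1 ^ S2 = empty} m1(S1) m2(S2).  Raises on total conflict.
    """
    if m1.n_classes != m2.n_classes:
        raise ValueError("mass functions defined over different frames")
    combined: dict[frozenset, float] = {}
    conflict = 0.0
    for h1, v1 in m1.masses.items():
        if v1 == 0:
            continue
        for h2, v2 in m2.masses.items():
            if v2 == 0:
                continue
            inter = h1 & h2
            prod = v1 * v2
            if inter:
                combined[inter] = combined.get(inter, 0.0) + prod
            else:
                conflict += prod
    if conflict >= 1.0 - _TOL:
        raise TotalConflictError(f"total conflict between sources (K={conflict})")
    norm = 1.0 - conflict
    combined = {h: v / norm for h, v in combined.items()}
    return MassFunction(combined, m1.n_classes), float(conflict)


def combine_all(masses: Sequence[MassFunction]) -> tuple[MassFunction, float]:
    """Fold Dempster's rule over n sources; returns the overall conflict of
    the final combination step chain (product of per-step normalizers)."""
    if not masses:
        raise ValueError("need at least one mass function")
    out = masses[0]
    total_norm = 1.0
    for m in masses[1:]:
        out, K = dempster_combine(out, m)
        total_norm *= 1.0 - K
    return out, float(1.0 - total_norm)


def decide(m: MassFunction) -> int:
    """Maximum-belief singleton decision; ties go to the lowest class index."""
    bels = np.array([m.belief({j}) for j in range(m.n_classes)])
    winners = np.flatnonzero(bels == bels.max())
    if len(winners) > 1:
        logger.info(
            "belief tie between classes %s; choosing the lowest index",
            winners.tolist(),
        )
    return int(winners[0])


# ---------------------------------------------------------------------------
# Relabeling (training-phase evidential targets)
# ---------------------------------------------------------------------------


@dataclass
class RelabeledSample:
    """Feature vector with an evidential target hypothesis."""

    x: np.ndarray
    target: frozenset
    memberships: np.ndarray

    def __post_init__(self) -> None:
        if len(self.target) == 0:
            raise ValueError("target hypothesis must be nonempty")


def class_prototypes(X: np.ndarray, y: Sequence) -> dict:
    """Per-class mean feature vectors (in whatever space X lives in)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    return {label: X[y == label].mean(axis=0) for label in np.unique(y)}


def relabel(
    x: Sequence[float],
    prototypes: Mapping,
    membership_threshold: float = 0.4,
    class_order: Sequence | None = None,
) -> RelabeledSample:
    """Membership-based evidential target for one training sample.

    Memberships are normalized inverse distances to the class prototypes
    (an exact prototype hit gets membership 1).  The target hypothesis is
    the set of classes with membership >= threshold, falling back to the
    argmax class when the thresholded set is empty.
    """
    if not 0.0 < membership_threshold < 1.0:
        raise ValueError("membership threshold must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    order = list(class_order) if class_order is not None else sorted(prototypes)
    d = np.array([np.linalg.norm(x - np.asarray(prototypes[c])) for c in order])
    zero = d <= 0
    if zero.any():
        w = zero.astype(float) / zero.sum()
    else:
        inv = 1.0 / d
        w = inv / inv.sum()
    members = frozenset(int(j) for j in np.flatnonzero(w >= membership_threshold))
    if not members:
        members = frozenset({int(np.argmax(w))})
    return RelabeledSample(x=x, target=members, memberships=w)


def _target_distribution(target: frozenset, n_classes: int) -> np.ndarray:
    t = np.zeros(n_classes)
    for j in target:
        t[j] = 1.0 / len(target)
    return t


class DempsterShaferClassifier(ClassifierMixin, BaseEstimator):
    """Quadrant classifier fusing per-subset MLPs with Dempster's rule.

    Parameters
    ----------
    feature_subsets : sequence of index sequences
        Column indices each base learner sees (two in the intended use:
        the arousal and the valence locality subsets; any number works).
    membership_threshold : float
        Relabeling threshold on prototype memberships.
    hidden_layer_sizes, activation, max_iter : MLP architecture.
    random_state : seeds the MLP weight initialisations.

    Fitted attributes: ``classes_``, ``mlps_``, ``scalers_`` (mean, std per
    subset), ``prototypes_`` (per subset, in the z-scored space).
    """

    def __init__(
        self,
        feature_subsets: Sequence[Sequence[int]] | None = None,
        membership_threshold: float = 0.4,
        hidden_layer_sizes: tuple = (20,),
        activation: str = "logistic",
        max_iter: int = 500,
        random_state: int | None = 0,
    ):
        self.feature_subsets = feature_subsets
        self.membership_threshold = membership_threshold
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_iter = max_iter
        self.random_state = random_state

    def _resolved_subsets(self, n_features: int) -> list[list[int]]:
        if self.feature_subsets is None:
            return [list(range(n_features))]
        subsets = [sorted(int(i) for i in s) for s in self.feature_subsets]
        if any(len(s) == 0 for s in subsets):
            raise ValueError("feature subsets must be nonempty")
        return subsets

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        subsets = self._resolved_subsets(X.shape[1])
        self.mlps_, self.scalers_, self.prototypes_ = [], [], []
        for si, subset in enumerate(subsets):
            Xi = X[:, subset]
            mean, std = Xi.mean(axis=0), Xi.std(axis=0)
            std[std == 0] = 1.0
            Z = (Xi - mean) / std
            protos = class_prototypes(Z, y_idx)
            # the evidential target softens the crisp label into a set: the
            # true class plus every class whose membership clears the
            # threshold (ambiguous samples get composite targets)
            targets = np.empty((len(Z), n_classes))
            for row, (z, yi) in enumerate(zip(Z, y_idx)):
                rs = relabel(
                    z, protos, self.membership_threshold,
                    class_order=range(n_classes),
                )
                members = frozenset(
                    int(j)
                    for j in np.flatnonzero(rs.memberships >= self.membership_threshold)
                ) | {int(yi)}
                targets[row] = _target_distribution(members, n_classes)
            seed = None if self.random_state is None else int(self.random_state) + si
            mlp = MLPRegressor(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation=self.activation,
                max_iter=self.max_iter,
                random_state=seed,
            )
            mlp.fit(Z, targets)
            self.mlps_.append(mlp)
            self.scalers_.append((mean, std))
            self.prototypes_.append(protos)
        self.subsets_ = subsets
        self.n_features_in_ = X.shape[1]
        return self

    def _source_scores(self, X: np.ndarray) -> list[np.ndarray]:
        X = np.asarray(X, dtype=float)
        scores = []
        for mlp, (mean, std), subset in zip(self.mlps_, self.scalers_, self.subsets_):
            Z = (X[:, subset] - mean) / std
            R = mlp.predict(Z)
            if R.ndim == 1:
                R = R[:, None]
            scores.append(R)
        return scores

    def predict_mass(self, X) -> list[tuple[MassFunction, float]]:
        """Per-sample fused mass function and conflict K."""
        check_is_fitted(self, "mlps_")
        scores = self._source_scores(np.asarray(X, dtype=float))
        out = []
        for i in range(len(scores[0])):
            masses = [softmax_mass(R[i]) for R in scores]
            fused, K = combine_all(masses)
            out.append((fused, K))
        return out

    def predict(self, X):
        return self.classes_[
            np.array([decide(m) for m, _ in self.predict_mass(X)], dtype=int)
        ]

    def predict_proba(self, X):
        """Fused singleton masses as a probability-like matrix."""
        out = np.zeros((len(X), len(self.classes_)))
        for i, (m, _) in enumerate(self.predict_mass(X)):
            for j in range(len(self.classes_)):
                out[i, j] = m.mass({j})
        rowsum = out.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return out / rowsum

    def source_predictions(self, X) -> list[np.ndarray]:
        """Per-source (single-MLP) decisions: softmax + max-Bel, no fusion."""
        check_is_fitted(self, "mlps_")
        return [
            self.classes_[
                np.array([decide(softmax_mass(r)) for r in R], dtype=int)
            ]
            for R in self._source_scores(np.asarray(X, dtype=float))
        ]
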