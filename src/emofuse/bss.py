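"""Second-order blind identification (SOBI) and channel activity maps.

SOBI separates a multichannel EEG epoch into components by (1) whitening the
channel covariance and (2) orthogonally joint-diagonalizing a set of
time-lagged covariance matrices of the whitened data with Jacobi-style
rotations.  Sources with distinct autocorrelation structure (oscillations at
different frequencies, coloured noise, band-limited chaos) are identifiable
up to permutation, sign and scale.

Channel-level "neural activity" is defined here as the energy-weighted
magnitude of the mixing topographies:

    activity(c) = sum_k |mixing[c, k]| * std(source_k)

i.e. how strongly any component expresses on channel ``c``, weighted by how
energetic that component is.  Per-class average maps are normalized by the
pooled peak magnitude so all values lie in [-1, 1] and the most active
channel of the dataset sits at +/-1; quiet channels stay near zero, which is
what makes absolute-value thresholding of "emotional channels" meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .quadrants import QUARTERS

__all__ = [
    "BSSResult",
    "ActivityMap",
    "sobi",
    "joint_diagonalize",
    "component_activity",
    "average_and_normalize",
    "activity_maps_by_class",
    "SOBI",
]


@dataclass
class BSSResult:
    """Mixing topographies and recovered sources of one epoch."""

    mixing: np.ndarray  # (n_channels, n_components)
    sources: np.ndarray  # (n_components, n_samples)
    method: str = "sobi"

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]


@dataclass
class ActivityMap:
    """Per-channel normalized activity of one emotion class, in [-1, 1]."""

    values: np.ndarray
    class_label: str
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.max(np.abs(self.values), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("normalized activity must lie in [-1, 1]")


def _lagged_cov(Z: np.ndarray, lag: int) -> np.ndarray:
    T = Z.shape[1]
    R = Z[:, lag:] @ Z[:, : T - lag].T / (T - lag)
    return 0.5 * (R + R.T)


def joint_diagonalize(
    mats: Sequence[np.ndarray], tol: float = 1e-8, max_sweeps: int = 200
) -> tuple[np.ndarray, list[float]]:
    """Orthogonal joint diagonalization by Jacobi rotations.

    Returns the rotation ``V`` minimizing the summed off-diagonal energy of
    ``V.T @ M @ V`` over the matrix set, and the off-diagonal energy after
    each sweep (non-increasing).

    The per-pair rotation angle is the closed-form Jacobi angle: for each
    matrix collect h = (M[p,p] - M[q,q], 2*M[p,q]); the optimal (cos, sin)
    comes from the dominant eigenvector of G = sum h h^T.
    """
    M = np.array([np.asarray(m, dtype=float) for m in mats])
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("expected a sequence of square matrices")
    n = M.shape[1]
    V = np.eye(n)

    def off_energy() -> float:
        total = 0.0
        for A in M:
            total += np.sum(A**2) - np.sum(np.diag(A) ** 2)
        return float(total)

    history = [off_energy()]
    for _ in range(max_sweeps):
        max_sin = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                h0 = M[:, p, p] - M[:, q, q]
                h1 = M[:, p, q] + M[:, q, p]
                G = np.array(
                    [
                        [h0 @ h0, h0 @ h1],
                        [h1 @ h0, h1 @ h1],
                    ]
                )
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, np.argmax(evals)]
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                if r <= 0:
                    continue
                c = np.sqrt((x + r) / (2 * r))
                s = y / np.sqrt(2 * r * (x + r))
                if abs(s) < tol:
                    continue
                max_sin = max(max_sin, abs(s))
                # rotate rows/cols p,q of every matrix and accumulate into V
                Mp = M[:, :, p].copy()
                Mq = M[:, :, q].copy()
                M[:, :, p] = c * Mp + s * Mq
                M[:, :, q] = -s * Mp + c * Mq
                Mp = M[:, p, :].copy()
                Mq = M[:, q, :].copy()
                M[:, p, :] = c * Mp + s * Mq
                M[:, q, :] = -s * Mp + c * Mq
                Vp = V[:, p].copy()
                V[:, p] = c * Vp + s * V[:, q]
                V[:, q] = -s * Vp + c * V[:, q]
        history.append(off_energy())
        if max_sin < tol:
            break
    return V, history


def sobi(
    epoch_data: np.ndarray,
    lags: Sequence[int] | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 200,
    rank_rtol: float = 1e-10,
) -> BSSResult:
    """SOBI decomposition of one channels x samples epoch.

    Channel means are removed and the data whitened before joint
    diagonalization of the lagged covariances.  Rank deficiency reduces the
    component count (with a warning).  The sign of each mixing column is fixed
    by making its largest-magnitude entry positive; components are ordered by
    decreasing energy.
    """
    X = np.asarray(epoch_data, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch data must be channels x samples")
    n_channels, T = X.shape
    if lags is None:
        lags = range(1, min(100, T // 4) + 1)
    lags = [int(l) for l in lags]
    if not lags or min(lags) < 1:
        raise ValueError("lags must be positive integers")
    if T <= max(lags) + 1:
        raise ValueError(
            f"signal too short ({T} samples) for the requested lags (max {max(lags)})"
        )

    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = Xc @ Xc.T / T
    evals, evecs = np.linalg.eigh(C0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals[0], 0.0) * rank_rtol
    rank = int(np.sum(keep))
    if rank == 0:
        raise ValueError("all-zero epoch: covariance has no positive eigenvalues")
    if rank < n_channels:
        warnings.warn(
            f"rank-deficient covariance: keeping {rank} of {n_channels} components",
            stacklevel=2,
        )
    evals, evecs = evals[:rank], evecs[:, :rank]
    W = evecs.T / np.sqrt(evals)[:, None]  # whitener, (rank, n_channels)
    Z = W @ Xc

    R = [_lagged_cov(Z, lag) for lag in lags]
    V, _ = joint_diagonalize(R, tol=tol, max_sweeps=max_sweeps)

    sources = V.T @ Z
    mixing = evecs * np.sqrt(evals)[None, :] @ V  # pinv(W) @ V

    # sign convention: largest-|.| entry of each mixing column positive
    flip = np.sign(mixing[np.argmax(np.abs(mixing), axis=0), np.arange(rank)])
    flip[flip == 0] = 1.0
    mixing = mixing * flip
    sources = sources * flip[:, None]

    energy = np.abs(mixing).sum(axis=0) * sources.std(axis=1)
    order = np.argsort(energy)[::-1]
    return BSSResult(mixing=mixing[:, order], sources=sources[order], method="sobi")


def component_activity(bss: BSSResult) -> np.ndarray:
    """Raw per-channel activity: |mixing| weighted by component energy."""
    return np.abs(bss.mixing) @ bss.sources.std(axis=1)


def average_and_normalize(
    maps: Sequence[np.ndarray],
    class_label: str,
    pooled_peak: float | None = None,
) -> ActivityMap:
    """Average per-epoch activity vectors and normalize by the pooled peak.

    ``pooled_peak`` is the maximum |activity| over the whole dataset's
    class-average maps; when normalizing a single class in isolation it
    defaults to this class's own peak.  The peak maps to +/-1, everything
    else scales proportionally, so values lie in [-1, 1].
    """
    if len(maps) == 0:
        raise ValueError("cannot average an empty list of activity maps")
    arr = np.asarray([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 2:
        raise ValueError("activity vectors must share a common length")
    mean = arr.mean(axis=0)
    peak = float(np.max(np.abs(mean))) if pooled_peak is None else float(pooled_peak)
    values = mean / peak if peak > 0 else np.zeros_like(mean)
    return ActivityMap(values=values, class_label=class_label, n_trials_averaged=len(maps))


def activity_maps_by_class(
    activity_vectors: Sequence[np.ndarray],
    class_labels: Sequence[str],
) -> dict[str, ActivityMap]:
    """Class-average activity maps normalized over the whole dataset.

    The normalizing peak is pooled across the four class-mean maps, so the
    classes stay on a common scale (the dataset's most active channel is 1).
    """
    if len(activity_vectors) != len(class_labels):
        raise ValueError("one class label per activity vector required")
    present = [q for q in QUARTERS if q in set(class_labels)] or sorted(set(class_labels))
    means = {}
    groups: dict[str, list[np.ndarray]] = {}
    for vec, lab in zip(activity_vectors, class_labels):
        groups.setdefault(lab, []).append(np.asarray(vec, dtype=float))
    for q in present:
        means[q] = np.mean(groups[q], axis=0)
    pooled_peak = max(float(np.max(np.abs(m))) for m in means.values())
    return {
        q: average_and_normalize(groups[q], q, pooled_peak=pooled_peak) for q in present
    }


class SOBI(TransformerMixin, BaseEstimator):
    """scikit-learn style SOBI transformer.

    Follows the decomposition conventions of ``sklearn.decomposition.FastICA``:
    ``X`` is (n_samples, n_channels) with time along the rows; ``transform``
    returns the recovered sources (n_samples, n_components).

    Attributes
    ----------
    mixing_ : ndarray of shape (n_channels, n_components)
    components_ : ndarray of shape (n_components, n_channels)
        Unmixing matrix applied to centred data.
    """

    def __init__(self, lags=None, tol: float = 1e-8, max_sweeps: int = 200):
        self.lags = lags
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        result = sobi(X.T, lags=self.lags, tol=self.tol, max_sweeps=self.max_sweeps)
        self.mixing_ = result.mixing
        self.mean_ = X.mean(axis=0)
        self.components_ = np.linalg.pinv(result.mixing)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T
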