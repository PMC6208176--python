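"""Nine nonlinear / entropy features per channel per epoch.

The feature set is the one most often reported for EEG affect decoding:

======  =============================================
CD      correlation dimension (Grassberger-Procaccia)
FD      Higuchi fractal dimension
LLE     largest Lyapunov exponent (Rosenstein), 1/s
SpEn    sample entropy
RR      recurrence rate
DET     determinism
L       average diagonal line length
ENT     diagonal line-length entropy (nats)
DeEn    differential entropy (Gaussian form), nats
======  =============================================

CD, LLE and the recurrence measures are computed on a delay embedding of
the signal; the embedding delay defaults to the first zero crossing of the
autocorrelation and the Theiler window to ``m * tau``.  The recurrence
threshold is set per epoch to a fixed recurrence rate so DET/L/ENT are
comparable across epochs.  Long signals are decimated to at most
``max_points`` phase-space points before embedding, which bounds the
quadratic pair computations without touching the broadband statistics
(SpEn, DeEn, FD are computed on the full-rate series).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .channels import ChannelSet
from .simulate import EEGEpoch

__all__ = [
    "PhaseSpace",
    "FeatureParams",
    "FEATURE_ABBREVS",
    "delay_embed",
    "autocorr_delay",
    "correlation_dimension",
    "higuchi_fd",
    "largest_lyapunov",
    "sample_entropy",
    "recurrence_matrix",
    "rqa",
    "differential_entropy",
    "extract_features",
    "channel_features",
]

FEATURE_ABBREVS = ("CD", "FD", "LLE", "SpEn", "RR", "DET", "L", "ENT", "DeEn")


@dataclass
class PhaseSpace:
    """Delay-embedded trajectory: row i = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""

    trajectory: np.ndarray
    m: int
    tau: int

    @property
    def n_points(self) -> int:
        return self.trajectory.shape[0]


def delay_embed(x: Sequence[float], m: int, tau: int) -> PhaseSpace:
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1 and m > 1:
        raise ValueError("need m >= 1 and tau >= 1")
    n_points = len(x) - (m - 1) * tau
    if n_points <= 0:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, tau={tau}"
        )
    if m == 1:
        return PhaseSpace(trajectory=x[:, None].copy(), m=1, tau=tau)
    idx = np.arange(n_points)[:, None] + tau * np.arange(m)[None, :]
    return PhaseSpace(trajectory=x[idx], m=m, tau=tau)


def autocorr_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """First zero crossing of the autocorrelation function (at least 1)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    if max_lag is None:
        max_lag = max(1, n // 4)
    denom = x @ x
    if denom <= 0:
        return 1
    for lag in range(1, min(max_lag, n - 1) + 1):
        if x[lag:] @ x[:-lag] <= 0:
            return lag
    return min(max_lag, n - 1)


def _pair_distances(ps: PhaseSpace, theiler: int = 0) -> np.ndarray:
    """Condensed upper-triangle distances with Theiler-window pairs set to nan."""
    D = pdist(ps.trajectory)
    if theiler > 0:
        n = ps.n_points
        # condensed index for pair (i, j), j > i
        mask = np.zeros(len(D), dtype=bool)
        for d in range(1, min(theiler, n - 1) + 1):
            i = np.arange(n - d)
            j = i + d
            mask[(i * (2 * n - i - 1)) // 2 + (j - i - 1)] = True
        D = D.copy()
        D[mask] = np.nan
    return D


def correlation_dimension(
    ps: PhaseSpace,
    radii: Sequence[float] | None = None,
    theiler: int = 0,
) -> float:
    """Grassberger-Procaccia slope of log C(r) vs log r.

    C(r) is the fraction of (Theiler-separated) point pairs closer than r.
    The default scaling region spans the 1st-10th percentiles of the pair
    distances, where edge effects are negligible for low-dimensional sets.
    Degenerate (constant) trajectories return 0.
    """
    if ps.n_points < 100:
        raise ValueError("correlation dimension needs at least 100 points")
    D = _pair_distances(ps, theiler)
    D = D[~np.isnan(D)]
    if len(D) == 0 or np.max(D) <= 0:
        return 0.0
    if radii is None:
        lo = np.quantile(D, 0.01)
        hi = np.quantile(D, 0.10)
        positive = D[D > 0]
        if len(positive) == 0:
            return 0.0
        lo = max(lo, float(np.min(positive)))
        if hi <= lo:
            hi = float(np.quantile(D, 0.5))
        if hi <= lo:
            return 0.0
        radii = np.geomspace(lo, hi, 8)
    radii = np.asarray(radii, dtype=float)
    C = np.array([np.mean(D <= r) for r in radii])
    good = C > 0
    if good.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(radii[good]), np.log(C[good]), 1)[0]
    return float(slope)


def higuchi_fd(x: Sequence[float], k_max: int = 10) -> float:
    """Higuchi's fractal dimension of a bounded series (1 for smooth, 2 for noise)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < k_max + 2:
        raise ValueError("series too short for the requested k_max")
    lengths = []
    ks = np.arange(1, k_max + 1)
    for k in ks:
        Lk = 0.0
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            Lk += dist * norm / k
        lengths.append(Lk / k)
    lengths = np.asarray(lengths)
    good = lengths > 0
    if good.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(1.0 / ks[good]), np.log(lengths[good]), 1)[0]
    return float(slope)


def largest_lyapunov(
    ps: PhaseSpace,
    fs: float = 1.0,
    theiler: int | None = None,
    n_follow: int = 15,
    fit_range: tuple[int, int] | None = None,
) -> float:
    """Largest Lyapunov exponent by the Rosenstein nearest-neighbour method.

    Each point is paired with its nearest neighbour outside the Theiler
    window; the slope of the mean log divergence over the initial expansion
    region, times ``fs``, estimates the exponent in 1/s (0 for periodic
    signals, positive for chaos and noise).
    """
    traj = ps.trajectory
    n = ps.n_points
    if theiler is None:
        theiler = ps.m * ps.tau
    if n <= 2 * (theiler + 1) + n_follow:
        raise ValueError("too few phase-space points for the divergence analysis")
    D = squareform(pdist(traj))
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= theiler
    D[band] = np.inf
    # neighbours must leave room to follow both trajectories forward
    last = n - n_follow
    D = D[:last, :last]
    nn = np.argmin(D, axis=1)
    d0 = D[np.arange(last), nn]
    valid = np.isfinite(d0)
    if valid.sum() < 10:
        raise ValueError("not enough valid neighbour pairs")
    i0 = np.flatnonzero(valid)
    j0 = nn[valid]
    eps = 1e-12
    mean_log = np.empty(n_follow + 1)
    for k in range(n_follow + 1):
        dk = np.linalg.norm(traj[i0 + k] - traj[j0 + k], axis=1)
        mean_log[k] = np.mean(np.log(dk + eps))
    if fit_range is None:
        fit_range = (1, max(2, n_follow // 2))
    k0, k1 = fit_range
    ks = np.arange(k0, k1 + 1)
    slope = np.polyfit(ks, mean_log[k0 : k1 + 1], 1)[0]
    return float(slope * fs)


def sample_entropy(x: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with tolerance ``r`` in units of the series SD.

    B counts pairs of length-m templates within tolerance (Chebyshev
    distance), A the same for length m+1; self-matches are excluded.
    Constant series have entropy 0 by convention; if no (m+1)-template pair
    matches, the maximum estimable value -ln(2 / ((N-m-1)(N-m))) is returned.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd
    n_templates = n - m  # both template lengths use N - m vectors
    t_m = delay_embed(x, m, 1).trajectory[:n_templates]
    t_m1 = delay_embed(x, m + 1, 1).trajectory
    tree_m = cKDTree(t_m)
    tree_m1 = cKDTree(t_m1)
    # ordered pairs within tol, including self-pairs; remove self, halve
    B = (tree_m.count_neighbors(tree_m, tol, p=np.inf) - n_templates) / 2
    A = (tree_m1.count_neighbors(tree_m1, tol, p=np.inf) - n_templates) / 2
    if B == 0:
        return 0.0
    if A == 0:
        return float(-np.log(2.0 / ((n - m - 1) * (n - m))))
    return float(-np.log(A / B))


def recurrence_matrix(ps: PhaseSpace, eps: float) -> np.ndarray:
    """Binary recurrence matrix: R[i,j] = 1 iff ||p_i - p_j|| <= eps."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    D = squareform(pdist(ps.trajectory))
    return (D <= eps).astype(np.uint8)


def eps_for_recurrence_rate(ps: PhaseSpace, rr_target: float = 0.02) -> float:
    """Distance threshold giving approximately the target off-diagonal RR."""
    D = pdist(ps.trajectory)
    if len(D) == 0:
        return 0.0
    return float(np.quantile(D, rr_target))


def _diagonal_line_lengths(R: np.ndarray) -> np.ndarray:
    """Lengths of all runs of 1s on the off-main diagonals (both triangles)."""
    n = R.shape[0]
    lengths: list[int] = []
    for k in range(1, n):
        for diag in (np.diagonal(R, k), np.diagonal(R, -k)):
            padded = np.concatenate(([0], diag, [0]))
            changes = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(changes == 1)
            ends = np.flatnonzero(changes == -1)
            lengths.extend((ends - starts).tolist())
    return np.asarray(lengths, dtype=int)


def rqa(R: np.ndarray, l_min: int = 2) -> tuple[float, float, float, float]:
    """Recurrence-rate, determinism, mean diagonal length, line entropy.

    RR is the density of recurrent points off the main diagonal.  DET is the
    fraction of those points lying on diagonal lines of length >= l_min; L
    the mean such line length; ENT the Shannon entropy (nats) of the line
    length histogram (lengths >= l_min).  With no qualifying lines, DET, L
    and ENT are 0 by convention.
    """
    R = np.asarray(R)
    n = R.shape[0]
    if R.ndim != 2 or R.shape[1] != n:
        raise ValueError("recurrence matrix must be square")
    if l_min < 2:
        raise ValueError("l_min must be >= 2")
    off_points = int(R.sum()) - int(np.trace(R))
    denom = n * n - n
    rr = off_points / denom if denom > 0 else 0.0
    if off_points == 0:
        return float(rr), 0.0, 0.0, 0.0
    lengths = _diagonal_line_lengths(R)
    long_lines = lengths[lengths >= l_min]
    if len(long_lines) == 0:
        return float(rr), 0.0, 0.0, 0.0
    det = float(long_lines.sum() / off_points)
    L = float(long_lines.mean())
    _, counts = np.unique(long_lines, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    return float(rr), det, L, ent


def differential_entropy(x: Sequence[float]) -> float:
    """Gaussian-form differential entropy 0.5*ln(2*pi*e*sigma^2), nats."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    var = x.var(ddof=1)
    if var <= 0:
        return -np.inf
    return float(0.5 * np.log(2.0 * np.pi * np.e * var))


@dataclass
class FeatureParams:
    """Extraction conventions (recorded alongside every feature table)."""

    m: int = 10
    tau: int | None = None  # None: first autocorrelation zero crossing
    max_points: int = 1000
    sampen_m: int = 2
    sampen_r: float = 0.2
    rr_target: float = 0.02
    l_min: int = 2
    k_max: int = 10
    lle_follow: int = 15

    def to_dict(self) -> dict:
        return asdict(self)


def channel_features(
    x: np.ndarray, fs: float, params: FeatureParams | None = None
) -> dict[str, float]:
    """All nine features of one channel's series."""
    params = params or FeatureParams()
    x = np.asarray(x, dtype=float)
    n = len(x)

    # decimate for the quadratic phase-space computations
    stride = max(1, int(np.ceil(n / params.max_points)))
    xd = x[::stride]
    fs_d = fs / stride

    tau = params.tau if params.tau is not None else autocorr_delay(xd)
    m = params.m
    # keep at least ~100 embedded points
    while m > 2 and len(xd) - (m - 1) * tau < 100:
        m -= 1
    while tau > 1 and len(xd) - (m - 1) * tau < 100:
        tau -= 1
    ps = delay_embed(xd, m, tau)
    theiler = m * tau

    cd = correlation_dimension(ps, theiler=theiler)
    fd = higuchi_fd(x, k_max=params.k_max)
    try:
        lle = largest_lyapunov(ps, fs=fs_d, theiler=theiler, n_follow=params.lle_follow)
    except ValueError:
        lle = np.nan
    spen = sample_entropy(x, m=params.sampen_m, r=params.sampen_r)
    eps = eps_for_recurrence_rate(ps, params.rr_target)
    R = recurrence_matrix(ps, eps)
    rr, det, L, ent = rqa(R, l_min=params.l_min)
    deen = differential_entropy(x)
    return {
        "CD": cd,
        "FD": fd,
        "LLE": lle,
        "SpEn": spen,
        "RR": rr,
        "DET": det,
        "L": L,
        "ENT": ent,
        "DeEn": deen,
    }


def extract_features(
    epochs: Iterable[EEGEpoch],
    channels: ChannelSet,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Feature table: one row per epoch, 9 features per selected channel.

    Columns are named ``<channel>_<abbrev>``; the label columns ``quarter``,
    ``arousal`` and ``valence`` are appended.  Any non-finite feature raises
    with the offending epoch/channel/feature named.
    """
    params = params or FeatureParams()
    rows = []
    index = []
    for ep in epochs:
        row: dict[str, float] = {}
        for c, lab in zip(channels.indices, channels.labels):
            feats = channel_features(ep.data[c], ep.fs, params)
            for abbrev, value in feats.items():
                if not np.isfinite(value):
                    raise ValueError(
                        f"non-finite feature {abbrev} for epoch {ep.trial_id}, "
                        f"channel {lab}"
                    )
                row[f"{lab}_{abbrev}"] = value
        row["quarter"] = ep.quarter
        row["arousal"] = ep.arousal
        row["valence"] = ep.valence
        rows.append(row)
        index.append(ep.trial_id)
    return pd.DataFrame(rows, index=index)
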