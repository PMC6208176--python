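"""Synthetic DEAP-like EEG epochs and planted-structure feature tables.

The real benchmark (32 subjects x 40 one-minute trials of 32-channel EEG at
128 Hz, each trial rated 1-9 for arousal and valence) is access-restricted,
so this module generates labelled multichannel epochs with the structural
properties every downstream stage depends on:

* class-dependent spatial mixing: each arousal-valence quadrant has a set of
  "active" channels driven with >= 3x the gain of inactive channels;
* oscillatory sources at EEG band frequencies plus a low-dimensional chaotic
  component (logistic map, band-limited by polyphase resampling), so the
  nonlinear phase-space features take non-degenerate values;
* class-coded dynamics on the channels shared by all four quadrants
  (chaos fraction and dominant rhythm follow arousal, signal amplitude and
  regularity follow valence), so the quadrants are separable from the
  channels that survive the cross-class intersection;
* additive Gaussian sensor noise at a configurable SNR;
* ratings drawn uniformly inside the quadrant's box of the 1-9 plane.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .quadrants import DEFAULT_CUTOFF, QUARTERS, quarter_of

__all__ = [
    "EEGEpoch",
    "SimConfig",
    "generate_epochs",
    "generate_local_feature_table",
    "generate_quadrant_feature_table",
    "default_channel_labels",
]

# Old 10-20 nomenclature (T3/T4/T5/T6), as used in the channel tables of the
# emotion-recognition literature this package targets.
_TEN_TWENTY_32 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "Cz",
    "C3", "C4", "T3", "T4", "T5", "T6", "P3", "P4",
    "Pz", "O1", "O2", "Oz", "FC1", "FC2", "FC5", "FC6",
    "CP1", "CP2", "CP5", "CP6", "PO3", "PO4", "AF3", "AF4",
]

#: samples below which entropy estimates become unreliable
MIN_RELIABLE_SAMPLES = 4000


def default_channel_labels(n_channels: int) -> list[str]:
    """First ``n_channels`` names of a 32-electrode 10-20 montage."""
    if n_channels <= len(_TEN_TWENTY_32):
        return list(_TEN_TWENTY_32[:n_channels])
    return list(_TEN_TWENTY_32) + [
        f"EX{i}" for i in range(n_channels - len(_TEN_TWENTY_32))
    ]


@dataclass
class EEGEpoch:
    """One trial: a channels x samples matrix plus its ratings and quadrant."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    trial_id: str
    arousal: float
    valence: float
    quarter: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be a 2-D channels x samples matrix")
        n_channels, n_samples = self.data.shape
        if n_channels < 2:
            raise ValueError("an epoch needs at least 2 channels")
        if len(self.channel_labels) != n_channels:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != n_channels:
            raise ValueError("duplicate channel labels")
        if n_samples < MIN_RELIABLE_SAMPLES:
            warnings.warn(
                f"epoch has {n_samples} samples; entropy features are only "
                f"reliable from {MIN_RELIABLE_SAMPLES} samples upward",
                stacklevel=2,
            )
        expected = quarter_of(self.arousal, self.valence)
        if self.quarter != expected:
            raise ValueError(
                f"quarter {self.quarter!r} inconsistent with ratings "
                f"(arousal={self.arousal}, valence={self.valence} -> {expected})"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _default_channel_map(n_channels: int) -> dict[str, set[int]]:
    """Shared core {0,1,2} in every quadrant plus one quadrant-specific extra."""
    if n_channels < 7:
        raise ValueError("default channel map needs at least 7 channels")
    core = {0, 1, 2}
    return {q: core | {3 + i} for i, q in enumerate(QUARTERS)}


@dataclass
class SimConfig:
    """Conditions of the synthetic study.

    Defaults are the scaled study conditions used throughout the test suite:
    8 channels, 40 trials per quadrant, 32-second windows at 128 Hz (4096
    samples, the minimum for stable entropy estimation), 15 dB SNR.
    """

    n_channels: int = 8
    n_samples: int = 4096
    fs: float = 128.0
    n_trials_per_class: int = 40
    class_channel_map: dict[str, set[int]] | None = None
    snr_db: float = 15.0
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF
    #: gain of channels outside a quadrant's active set (active gain is 1.0,
    #: so the active:inactive amplitude ratio is 1/background_gain >= 3)
    background_gain: float = 0.2

    def resolved_channel_map(self) -> dict[str, set[int]]:
        cmap = self.class_channel_map
        if cmap is None:
            cmap = _default_channel_map(self.n_channels)
        cmap = {q: set(cmap[q]) for q in QUARTERS}
        for q, chans in cmap.items():
            if not chans:
                raise ValueError(f"active channel set for {q} is empty")
            for c in chans:
                if not (0 <= int(c) < self.n_channels):
                    raise ValueError(
                        f"channel index {c} in class_channel_map[{q!r}] out of "
                        f"range [0, {self.n_channels})"
                    )
        return cmap

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if not 0 < self.background_gain < 1 / 3 + 1e-9:
            raise ValueError("background_gain must lie in (0, 1/3]")
        self.resolved_channel_map()


def _logistic_series(rng: np.random.Generator, n: int, r: float = 4.0) -> np.ndarray:
    """Band-limited chaos: a logistic-map orbit resampled 4x to the target rate."""
    n_raw = max(n // 4 + 8, 16)
    x = np.empty(n_raw)
    x[0] = rng.uniform(0.2, 0.8)
    for i in range(1, n_raw):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    y = resample_poly(x - x.mean(), 4, 1)[:n]
    if len(y) < n:  # pragma: no cover - resample_poly returns >= 4*(n_raw)-ish
        y = np.pad(y, (0, n - len(y)), mode="wrap")
    return _unit(y)


def _oscillation(
    rng: np.random.Generator, n: int, fs: float, f0: float, n_partials: int = 3
) -> np.ndarray:
    """Sum of a few sinusoids around a dominant frequency, random phases."""
    t = np.arange(n) / fs
    sig = np.zeros(n)
    amps = (1.0, 0.5, 0.3)
    for i in range(n_partials):
        f = f0 * (1.0 + 0.12 * i) * (1.0 + rng.uniform(-0.03, 0.03))
        sig += amps[i % 3] * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return _unit(sig)


def _unit(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return x / s if s > 0 else x


def _mix(weights_and_signals: list[tuple[float, np.ndarray]]) -> np.ndarray:
    out = sum(w * s for w, s in weights_and_signals)
    return _unit(out)


def _epoch_signals(
    rng: np.random.Generator, cfg: SimConfig, quarter: str, shared: list[int],
    extras: dict[str, set[int]],
) -> np.ndarray:
    """Build the noiseless channels x samples matrix for one trial."""
    n, fs = cfg.n_samples, cfg.fs
    high_a = quarter in ("Q1", "Q2")
    high_v = quarter in ("Q1", "Q4")

    # per-quadrant dominant rhythm for the quadrant-specific channels
    f_q = {"Q1": 24.0, "Q2": 18.0, "Q3": 5.0, "Q4": 11.0}[quarter]
    # scale the rhythms down if the sampling rate cannot carry them
    nyq = fs / 2.0
    scale_f = min(1.0, nyq / 40.0)

    chaos = _logistic_series(rng, n)
    chaos2 = _logistic_series(rng, n)

    data = np.empty((cfg.n_channels, n))
    active = set(shared) | extras.get(quarter, set())
    for c in range(cfg.n_channels):
        role = shared.index(c) if c in shared else None
        if role == 0:
            # arousal-coded dynamics: chaos fraction 0.75 (high) vs 0.25 (low)
            w = 0.75 if high_a else 0.25
            sig = _mix([(1 - w, _oscillation(rng, n, fs, 10.0 * scale_f)), (w, chaos)])
        elif role == 1:
            # arousal-coded rhythm: beta-range (high) vs theta-range (low)
            f = (20.0 if high_a else 7.0) * scale_f
            sig = _mix([(0.8, _oscillation(rng, n, fs, f)), (0.2, chaos2)])
        elif role == 2:
            # valence-coded amplitude and regularity
            w = 0.55 if high_v else 0.25
            amp = 1.8 if high_v else 1.0
            sig = amp * _mix(
                [(1 - w, _oscillation(rng, n, fs, 9.0 * scale_f)), (w, chaos2)]
            )
        elif role is not None or c in active:
            # quadrant-specific (or surplus shared) active channel
            sig = _mix([(1.0, _oscillation(rng, n, fs, f_q * scale_f)), (0.5, chaos)])
        else:
            # background channel: low-gain generic mixture
            sig = cfg.background_gain * _mix(
                [(1.0, _oscillation(rng, n, fs, 8.0 * scale_f)), (0.4, chaos2)]
            )
        data[c] = sig
    return data


def generate_epochs(cfg: SimConfig) -> list[EEGEpoch]:
    """Generate ``4 * n_trials_per_class`` labelled epochs.

    For each quadrant the active channels of ``class_channel_map`` carry the
    quadrant's sources with >= 3x the gain of inactive channels (before
    noise); ratings are drawn uniformly inside the quadrant's box.
    """
    cfg.validate()
    cmap = cfg.resolved_channel_map()
    shared = sorted(set.intersection(*(cmap[q] for q in QUARTERS)))
    extras = {q: cmap[q] - set(shared) for q in QUARTERS}
    labels = default_channel_labels(cfg.n_channels)
    rng = np.random.default_rng(cfg.seed)

    lo, hi, cut = 1.0, 9.0, cfg.cutoff
    epochs: list[EEGEpoch] = []
    for q in QUARTERS:
        high_a = q in ("Q1", "Q2")
        high_v = q in ("Q1", "Q4")
        for t in range(cfg.n_trials_per_class):
            arousal = rng.uniform(cut, hi) if high_a else rng.uniform(lo, cut)
            valence = rng.uniform(cut, hi) if high_v else rng.uniform(lo, cut)
            # the uniform draw can land exactly on the cutoff (prob. 0, but be safe)
            if quarter_of(arousal, valence, cut) != q:  # pragma: no cover
                arousal = arousal + 1e-6 if high_a else arousal
                valence = valence + 1e-6 if high_v else valence
            data = _epoch_signals(rng, cfg, q, shared, extras)
            sigma = data.std(axis=1, keepdims=True)
            noise = rng.standard_normal(data.shape)
            data = data + sigma * 10.0 ** (-cfg.snr_db / 20.0) * noise
            with warnings.catch_warnings():
                if cfg.n_samples < MIN_RELIABLE_SAMPLES:
                    warnings.simplefilter("ignore")
                epochs.append(
                    EEGEpoch(
                        data=data,
                        fs=cfg.fs,
                        channel_labels=list(labels),
                        trial_id=f"{q}_t{t:03d}",
                        arousal=float(arousal),
                        valence=float(valence),
                        quarter=q,
                    )
                )
    return epochs


def generate_local_feature_table(
    n_samples: int,
    n_features: int,
    planted: tuple[set[int], set[int], int],
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with planted two-locality structure.

    The sample space splits at 0 on the splitting feature; the binary label on
    the left partition (splitting feature <= 0) is the sign of the sum of the
    left planted set, on the right that of the right planted set.  All other
    features are label-independent N(0,1) noise.

    Returns a DataFrame with columns ``f0..f{F-1}`` plus ``label``.
    """
    left_set, right_set, split_feature = planted
    left_set, right_set = set(left_set), set(right_set)
    if left_set & right_set:
        raise ValueError("planted feature sets must be disjoint")
    for f in left_set | right_set | {split_feature}:
        if not (0 <= int(f) < n_features):
            raise ValueError(f"planted feature index {f} out of range")
    if split_feature in left_set | right_set:
        raise ValueError("splitting feature cannot be a planted predictor")
    columns = [f"f{i}" for i in range(n_features)]
    if n_samples == 0:
        return pd.DataFrame(columns=columns + ["label"])
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    left_mask = X[:, split_feature] <= 0.0
    y = np.where(
        left_mask,
        (X[:, sorted(left_set)].sum(axis=1) > 0),
        (X[:, sorted(right_set)].sum(axis=1) > 0),
    ).astype(int)
    out = pd.DataFrame(X, columns=columns)
    out["label"] = y
    return out


def generate_quadrant_feature_table(
    n_samples: int,
    n_features: int,
    arousal_set: set[int],
    valence_set: set[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table whose arousal/valence labels depend on two planted sets.

    High arousal iff the arousal set's features sum positive, likewise for
    valence; ratings are drawn uniformly inside the implied half of the 1-9
    scale and the quadrant label is derived from them.
    """
    arousal_set, valence_set = set(arousal_set), set(valence_set)
    if arousal_set & valence_set:
        raise ValueError("planted feature sets must be disjoint")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    high_a = X[:, sorted(arousal_set)].sum(axis=1) > 0
    high_v = X[:, sorted(valence_set)].sum(axis=1) > 0
    arousal = np.where(high_a, rng.uniform(5.5, 8.5, n_samples), rng.uniform(1.5, 4.5, n_samples))
    valence = np.where(high_v, rng.uniform(5.5, 8.5, n_samples), rng.uniform(1.5, 4.5, n_samples))
    out = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    out["arousal"] = arousal
    out["valence"] = valence
    out["quarter"] = [quarter_of(a, v) for a, v in zip(arousal, valence)]
    return out

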