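"""Artifact reading/writing: epoch directories, feature tables, model bundles.

Epoch sets are a directory of per-trial CSV matrices (channels x samples)
plus a JSON manifest carrying trial ids, ratings, quadrant labels, sampling
rate and channel names.  Feature tables are CSV with a sidecar JSON of the
extraction parameters.  Trained models are a single JSON bundle (MLP
weights as nested lists) so every artifact stays plain text.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dst import DempsterShaferClassifier
from .features import FeatureParams
from .simulate import EEGEpoch, MIN_RELIABLE_SAMPLES

__all__ = [
    "save_epochs",
    "load_epochs",
    "load_deap_subject",
    "save_feature_table",
    "load_feature_table",
    "save_model_bundle",
    "load_model_bundle",
    "config_hash",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_epochs(epochs: Sequence[EEGEpoch], directory: str | Path, meta: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"epochs": [], "meta": meta or {}}
    for ep in epochs:
        fname = f"{ep.trial_id}.csv"
        np.savetxt(directory / fname, ep.data, delimiter=",")
        manifest["epochs"].append(
            {
                "trial_id": ep.trial_id,
                "file": fname,
                "fs": ep.fs,
                "channel_labels": ep.channel_labels,
                "arousal": ep.arousal,
                "valence": ep.valence,
                "quarter": ep.quarter,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_epochs(directory: str | Path) -> list[EEGEpoch]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"no manifest.json in {directory}; run the simulate stage first"
        )
    manifest = json.loads(manifest_path.read_text())
    epochs = []
    for entry in manifest["epochs"]:
        data = np.loadtxt(directory / entry["file"], delimiter=",")
        with warnings.catch_warnings():
            if data.shape[-1] < MIN_RELIABLE_SAMPLES:
                warnings.simplefilter("ignore")
            epochs.append(
                EEGEpoch(
                    data=np.atleast_2d(data),
                    fs=entry["fs"],
                    channel_labels=entry["channel_labels"],
                    trial_id=entry["trial_id"],
                    arousal=entry["arousal"],
                    valence=entry["valence"],
                    quarter=entry["quarter"],
                )
            )
    return epochs


def load_deap_subject(
    path: str | Path,
    subject_id: str | None = None,
    fs: float = 128.0,
    n_eeg_channels: int = 32,
    channel_labels: Sequence[str] | None = None,
) -> list[EEGEpoch]:
    """Adapter for preprocessed per-subject MATLAB files of rated-trial EEG.

    Expects the layout of the common preprocessed distribution: ``data`` of
    shape (n_trials, n_channels, n_samples) with the EEG channels first, and
    ``labels`` of shape (n_trials, >=2) whose first two columns are the
    valence and arousal ratings on the 1-9 scale.
    """
    from scipy.io import loadmat

    path = Path(path)
    mat = loadmat(path)
    if "data" not in mat or "labels" not in mat:
        raise ValueError(f"{path} lacks the expected 'data'/'labels' variables")
    data = np.asarray(mat["data"], dtype=float)
    ratings = np.asarray(mat["labels"], dtype=float)
    if data.ndim != 3 or ratings.ndim != 2 or len(ratings) != len(data):
        raise ValueError("unexpected shapes for 'data'/'labels'")
    if channel_labels is None:
        from .simulate import default_channel_labels

        channel_labels = default_channel_labels(n_eeg_channels)
    sid = subject_id or path.stem
    epochs = []
    from .quadrants import quarter_of

    for trial in range(len(data)):
        valence, arousal = float(ratings[trial, 0]), float(ratings[trial, 1])
        epochs.append(
            EEGEpoch(
                data=data[trial, :n_eeg_channels, :],
                fs=fs,
                channel_labels=list(channel_labels),
                trial_id=f"{sid}_t{trial:02d}",
                arousal=arousal,
                valence=valence,
                quarter=quarter_of(arousal, valence),
            )
        )
    return epochs


def save_feature_table(
    table: pd.DataFrame, path: str | Path, params: FeatureParams | None = None,
    extra_meta: dict | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="trial_id")
    sidecar = {"params": (params or FeatureParams()).to_dict()}
    sidecar.update(extra_meta or {})
    path.with_suffix(".params.json").write_text(json.dumps(sidecar, indent=1))


def load_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"no feature table at {path}; run the extract-features stage first"
        )
    return pd.read_csv(path, index_col="trial_id")


def save_model_bundle(
    clf: DempsterShaferClassifier,
    path: str | Path,
    feature_names: Sequence[str],
    meta: dict | None = None,
) -> None:
    """Persist a fitted classifier (weights, scalers, prototypes) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sources = []
    for mlp, (mean, std), protos, subset in zip(
        clf.mlps_, clf.scalers_, clf.prototypes_, clf.subsets_
    ):
        sources.append(
            {
                "subset": [int(i) for i in subset],
                "scaler_mean": mean.tolist(),
                "scaler_std": std.tolist(),
                "prototypes": {str(k): v.tolist() for k, v in protos.items()},
                "coefs": [w.tolist() for w in mlp.coefs_],
                "intercepts": [b.tolist() for b in mlp.intercepts_],
                "activation": mlp.activation,
            }
        )
    bundle = {
        "format_version": 1,
        "classes": [str(c) for c in clf.classes_],
        "membership_threshold": clf.membership_threshold,
        "hidden_layer_sizes": list(clf.hidden_layer_sizes),
        "feature_names": list(feature_names),
        "sources": sources,
        "meta": meta or {},
    }
    path.write_text(json.dumps(bundle, indent=1))


class _FrozenMLP:
    """Forward pass of a persisted MLPRegressor (logistic/tanh/relu hidden)."""

    def __init__(self, coefs, intercepts, activation):
        self.coefs = [np.asarray(w) for w in coefs]
        self.intercepts = [np.asarray(b) for b in intercepts]
        self.activation = activation

    def predict(self, Z: np.ndarray) -> np.ndarray:
        h = np.asarray(Z, dtype=float)
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            h = h @ W + b
            if i < len(self.coefs) - 1:
                if self.activation == "logistic":
                    h = 1.0 / (1.0 + np.exp(-h))
                elif self.activation == "tanh":
                    h = np.tanh(h)
                elif self.activation == "relu":
                    h = np.maximum(h, 0.0)
                else:  # identity
                    pass
        return h


def load_model_bundle(path: str | Path) -> DempsterShaferClassifier:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"no model bundle at {path}; run the train stage first"
        )
    bundle = json.loads(path.read_text())
    clf = DempsterShaferClassifier(
        feature_subsets=[s["subset"] for s in bundle["sources"]],
        membership_threshold=bundle["membership_threshold"],
        hidden_layer_sizes=tuple(bundle["hidden_layer_sizes"]),
    )
    clf.classes_ = np.array(bundle["classes"])
    clf.subsets_ = [s["subset"] for s in bundle["sources"]]
    clf.scalers_ = [
        (np.asarray(s["scaler_mean"]), np.asarray(s["scaler_std"]))
        for s in bundle["sources"]
    ]
    clf.prototypes_ = [
        {int(k): np.asarray(v) for k, v in s["prototypes"].items()}
        for s in bundle["sources"]
    ]
    clf.mlps_ = [
        _FrozenMLP(s["coefs"], s["intercepts"], s["activation"])
        for s in bundle["sources"]
    ]
    clf.n_features_in_ = len(bundle["feature_names"])
    return clf
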