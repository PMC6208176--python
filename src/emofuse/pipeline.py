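"""Stage orchestration: a YAML config drives the end-to-end chain.

Stages (each writes versioned artifacts plus a JSON log of parameters and
the config hash): simulate, select-channels, extract-features,
select-features, train, predict, evaluate, all.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bss, channels as channels_mod, features as features_mod, io
from .dst import DempsterShaferClassifier
from .evaluation import PipelineSettings, confusion, confidence, cross_validate_pipeline
from .feature_tree import ScoreConfig, two_locality_subsets
from .quadrants import QUARTERS, binarize_arousal, binarize_valence
from .simulate import SimConfig, generate_epochs

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "select-channels",
    "extract-features",
    "select-features",
    "train",
    "predict",
    "evaluate",
    "all",
)


@dataclass
class PipelineConfig:
    """Serializable configuration of every stage."""

    out_dir: str = "emofuse_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    channel_threshold: float = 0.4
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

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["class_channel_map"] = (
            None
            if self.sim.class_channel_map is None
            else {q: sorted(v) for q, v in self.sim.class_channel_map.items()}
        )
        d["hidden_layer_sizes"] = list(self.hidden_layer_sizes)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if sim_d.get("class_channel_map"):
            sim_d["class_channel_map"] = {
                q: set(v) for q, v in sim_d["class_channel_map"].items()
            }
        fp_d = dict(d.pop("feature_params", {}))
        cfg = PipelineConfig(
            sim=SimConfig(**sim_d),
            feature_params=features_mod.FeatureParams(**fp_d),
            **d,
        )
        cfg.hidden_layer_sizes = tuple(cfg.hidden_layer_sizes)
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def settings(self) -> PipelineSettings:
        return PipelineSettings(
            channel_threshold=self.channel_threshold,
            feature_params=self.feature_params,
            knn_k=self.knn_k,
            search_budget=self.search_budget,
            search_max_depth=self.search_max_depth,
            n_keep=self.n_keep,
            membership_threshold=self.membership_threshold,
            hidden_layer_sizes=self.hidden_layer_sizes,
            mlp_max_iter=self.mlp_max_iter,
            n_folds=self.n_folds,
            seed=self.seed,
        )


def _write_log(out: Path, stage: str, cfg: PipelineConfig, extra: dict | None = None) -> None:
    log = {"stage": stage, "config_hash": io.config_hash(cfg.to_dict()), "seed": cfg.seed}
    log.update(extra or {})
    (out / f"{stage}.log.json").write_text(json.dumps(log, indent=1, default=str))


def _feature_matrix(table, feature_cols):
    return table[feature_cols].to_numpy(dtype=float), feature_cols


def run_stage(stage: str, cfg: PipelineConfig) -> Path:
    """Run one named stage (or ``all``); returns the output directory."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if stage == "all":
        for s in STAGES[:-1]:
            run_stage(s, cfg)
        return out

    if stage == "simulate":
        epochs = generate_epochs(cfg.sim)
        io.save_epochs(epochs, out / "epochs", meta={"config_hash": io.config_hash(cfg.to_dict())})
        _write_log(out, stage, cfg, {"n_epochs": len(epochs)})
        return out

    epochs = io.load_epochs(out / "epochs")
    labels = epochs[0].channel_labels

    if stage == "select-channels":
        activity = [bss.component_activity(bss.sobi(ep.data)) for ep in epochs]
        maps = bss.activity_maps_by_class(activity, [ep.quarter for ep in epochs])
        sets = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for q in QUARTERS:
                sets[q] = channels_mod.select_emotional_channels(
                    maps[q], cfg.channel_threshold, labels
                )
            common = channels_mod.intersect_channels([sets[q] for q in QUARTERS])
        payload = {
            "threshold": cfg.channel_threshold,
            "activity": {q: maps[q].values.tolist() for q in QUARTERS},
            "per_class": {
                q: {"indices": list(sets[q].indices), "labels": list(sets[q].labels)}
                for q in QUARTERS
            },
            "intersection": {
                "indices": list(common.indices),
                "labels": list(common.labels),
            },
        }
        (out / "channels.json").write_text(json.dumps(payload, indent=1))
        _write_log(out, stage, cfg, {"n_selected": len(common)})
        return out

    if stage == "extract-features":
        chan_file = out / "channels.json"
        if not chan_file.exists():
            raise FileNotFoundError(
                "channels.json missing; run the select-channels stage first"
            )
        sel = json.loads(chan_file.read_text())["intersection"]
        chan_set = channels_mod.ChannelSet(
            indices=tuple(sel["indices"]), labels=tuple(sel["labels"]),
            class_label="intersection",
        )
        table = features_mod.extract_features(epochs, chan_set, cfg.feature_params)
        io.save_feature_table(
            table, out / "features.csv", cfg.feature_params,
            {"config_hash": io.config_hash(cfg.to_dict())},
        )
        _write_log(out, stage, cfg, {"n_rows": len(table), "n_cols": table.shape[1]})
        return out

    table = io.load_feature_table(out / "features.csv")
    feature_cols = [c for c in table.columns if c not in ("quarter", "arousal", "valence")]
    X, _ = _feature_matrix(table, feature_cols)
    y = table["quarter"].to_numpy()
    y_a = np.array([binarize_arousal(a) for a in table["arousal"]])
    y_v = np.array([binarize_valence(v) for v in table["valence"]])

    if stage == "select-features":
        a_sub, v_sub = two_locality_subsets(
            X, y_a, y_v, cfg=ScoreConfig(k=cfg.knn_k), budget=cfg.search_budget,
            max_depth=cfg.search_max_depth, n_keep=cfg.n_keep, seed=cfg.seed,
        )
        payload = {
            "arousal": [feature_cols[i] for i in a_sub],
            "valence": [feature_cols[i] for i in v_sub],
            "config_hash": io.config_hash(cfg.to_dict()),
        }
        (out / "subsets.json").write_text(json.dumps(payload, indent=1))
        _write_log(out, stage, cfg)
        return out

    if stage in ("train", "predict"):
        subs_file = out / "subsets.json"
        if not subs_file.exists():
            raise FileNotFoundError(
                "subsets.json missing; run the select-features stage first"
            )
        subs = json.loads(subs_file.read_text())
        a_idx = [feature_cols.index(c) for c in subs["arousal"]]
        v_idx = [feature_cols.index(c) for c in subs["valence"]]

        if stage == "train":
            clf = DempsterShaferClassifier(
                feature_subsets=[a_idx, v_idx],
                membership_threshold=cfg.membership_threshold,
                hidden_layer_sizes=cfg.hidden_layer_sizes,
                max_iter=cfg.mlp_max_iter,
                random_state=cfg.seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X, y)
            io.save_model_bundle(
                clf, out / "model.json", feature_cols,
                meta={"config_hash": io.config_hash(cfg.to_dict())},
            )
            _write_log(out, stage, cfg)
            return out

        clf = io.load_model_bundle(out / "model.json")
        rows = []
        for trial, (m, K), pred in zip(
            table.index, clf.predict_mass(X), clf.predict(X)
        ):
            row = {"trial_id": trial, "decision": pred, "conflict_K": K}
            for j, q in enumerate(clf.classes_):
                row[f"mass_{q}"] = m.mass({j})
            rows.append(row)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "decisions.csv", index=False)
        _write_log(out, stage, cfg)
        return out

    # stage == "evaluate": cross-validated end-to-end evaluation
    result = cross_validate_pipeline(epochs, cfg.settings())
    (out / "report.md").write_text(result.report() + "\n")
    result.pooled.to_frame().to_csv(out / "confusion.csv")
    np.savetxt(out / "confidence.csv", confidence(result.pooled), delimiter=",", fmt="%.4f")
    _write_log(out, stage, cfg, {"pooled_ccr": result.pooled_ccr})
    return out
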