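"""End-to-end driver: simulate -> preprocess -> beats -> features ->
dataset -> train -> evaluate, with config, artifact and provenance handling.

A run is a pure function of its resolved config (which embeds one global
seed). The global seed fans out into per-stage sub-seeds recorded in the
run manifest, and every written artifact is content-hashed so reruns can be
checked for bit-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beats as beats_mod
from . import dataset as dataset_mod
from . import features as features_mod
from . import model as model_mod
from . import preprocess, synthetic

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "seed": 0,
        "n_recordings": 10,
        "seizures_per_recording": 2,
        "preictal_lead_s": 60.0,
        "generator": {},  # GeneratorParams overrides
        "filters": {
            "ecg": {"low_hz": 0.4, "high_hz": 20.0, "order": 4, "smooth_ms": 12.0},
            "ppg": {"low_hz": 0.4, "high_hz": 3.0, "order": 4},
            "eeg": {"low_hz": 0.5, "high_hz": 40.0, "order": 4},
        },
        "dataset": {"train_frac": 0.7, "normalization": "per_recording"},
        "model": {"family": "boosted_trees", "k_folds": 5, "budget": 1},
        "save_recordings": False,
    }


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(default_config())

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic fan-out of the global seed into stage seeds (< 2^31)."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _filter_spec(cfg: dict) -> preprocess.FilterSpec:
    return preprocess.FilterSpec(
        low_cut_hz=cfg["low_hz"],
        high_cut_hz=cfg["high_hz"],
        order=cfg.get("order", 4),
        smoothing_window_ms=cfg.get("smooth_ms"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def process_recording(
    rec: synthetic.Recording, filters_cfg: dict
) -> tuple[beats_mod.BeatSeries, pd.DataFrame]:
    """Preprocess one recording and extract its beat series and unlabeled
    window feature table."""
    fs = rec.fs
    ecg_f = preprocess.preprocess_ecg(rec.ecg, fs, _filter_spec(filters_cfg["ecg"]))
    ppg_f = preprocess.preprocess_ppg(rec.ppg, fs, _filter_spec(filters_cfg["ppg"]))
    eeg_spec = _filter_spec(filters_cfg["eeg"])
    eeg_f = tuple(preprocess.preprocess_eeg(ch, fs, eeg_spec) for ch in rec.eeg)
    series = beats_mod.extract_beat_series(ecg_f, ppg_f, fs)
    table = features_mod.extract_feature_table(series, eeg_f, fs)
    return series, table


def build_labeled_table(
    rec: synthetic.Recording,
    filters_cfg: dict,
    normalization: str = "per_recording",
    recording_id: str = "rec0",
) -> pd.DataFrame:
    """Feature table with labels for one annotated recording; feature columns
    are z-scored within the recording when normalization='per_recording'."""
    if rec.annotations is None:
        raise PipelineError("features", "recording has no state annotations")
    _, table = process_recording(rec, filters_cfg)
    if table.empty:
        raise PipelineError("features", "no valid windows extracted")
    table = dataset_mod.label_feature_table(table, rec.annotations)
    if normalization == "per_recording":
        cols = list(features_mod.FEATURE_NAMES)
        z, _ = features_mod.zscore_normalize(table[cols].to_numpy(float))
        table[cols] = z
    table["recording"] = recording_id
    return table


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> Path:
    """Execute the full pipeline and write artifacts + manifest to out_dir."""
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    n_rec = cfg["n_recordings"]
    seeds = _sub_seeds(cfg["seed"], n_rec + 4)
    rec_seeds, shuffle_seed, rus_seed, split_seed, model_seed = (
        seeds[:n_rec], seeds[n_rec], seeds[n_rec + 1], seeds[n_rec + 2], seeds[n_rec + 3],
    )

    protocol = synthetic.ProtocolSpec()
    tables = []
    for i, rec_seed in enumerate(rec_seeds):
        stage = f"simulate[{i}]"
        try:
            params = synthetic.GeneratorParams(**cfg["generator"]).with_seed(rec_seed)
            rng = np.random.default_rng([rec_seed, 0x5E1])
            seizures = synthetic.sample_seizures(
                rng, cfg["seizures_per_recording"], protocol
            ) if cfg["seizures_per_recording"] > 0 else []
            rec, truth = synthetic.generate_recording(
                protocol, seizures, params, cfg["preictal_lead_s"]
            )
            if cfg["save_recordings"]:
                synthetic.write_recording(rec, truth, out / f"rec{i}")
            stage = f"features[{i}]"
            tables.append(
                build_labeled_table(
                    rec, cfg["filters"], cfg["dataset"]["normalization"], f"rec{i}"
                )
            )
        except (synthetic.GeneratorError, preprocess.FilterError,
                beats_mod.UnusableSegmentError, features_mod.FeatureError,
                dataset_mod.DatasetError, PipelineError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    try:
        pooled = dataset_mod.pool_and_shuffle(tables, shuffle_seed)
        pooled.to_csv(out / "dataset.csv", index=False, float_format="%.10g")
        train, valid = dataset_mod.stratified_split(
            pooled, cfg["dataset"]["train_frac"], split_seed
        )
        train = dataset_mod.rus_balance(train, rus_seed)
    except dataset_mod.DatasetError as exc:
        raise PipelineError("dataset", str(exc)) from exc

    try:
        X_train, y_train = dataset_mod.split_xy(train)
        X_valid, y_valid = dataset_mod.split_xy(valid)
        if cfg["dataset"]["normalization"] == "global":
            z_train, scaler = features_mod.zscore_normalize(X_train)
            X_train, X_valid = z_train, scaler.transform(X_valid)
        mcfg = cfg["model"]
        budget = mcfg.get("budget", 1)
        if budget > 1:
            best = model_mod.optimize_hyperparams(
                X_train, y_train, mcfg["family"], budget, model_seed, mcfg["k_folds"]
            )
            hyperparams = best.hyperparams
        else:
            hyperparams = {}
        config_t = model_mod.TrainConfig(
            family=mcfg["family"], k_folds=mcfg["k_folds"], budget=budget,
            seed=model_seed, hyperparams=hyperparams,
        )
        clf, _ = model_mod.crossval_train(X_train, y_train, config_t)
        report = model_mod.evaluate(clf, X_valid, y_valid)
        report.cv_fold_accuracy = clf.cv_scores_
    except model_mod.ModelError as exc:
        raise PipelineError("train", str(exc)) from exc

    report_payload = report.to_dict()
    report_payload["class_counts"] = {
        "train": train["label"].value_counts().to_dict(),
        "validation": valid["label"].value_counts().to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report_payload, indent=2, sort_keys=True))

    manifest = {
        "sub_seeds": {
            "recordings": rec_seeds, "shuffle": shuffle_seed, "rus": rus_seed,
            "split": split_seed, "model": model_seed,
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
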