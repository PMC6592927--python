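"""End-to-end stages: extract features to CSV, train/evaluate with manifests.

The two library entry points mirror the development workflow: descriptors
are extracted once per image into a flat CSV (`path,label,f0..f815`), then a
model is trained and evaluated with repeated stratified 70/30 splits, the
held-out predictions pooled across repeats into one confusion matrix plus
per-repeat accuracies (mean and SD).  Every output is accompanied by a run
manifest sufficient to re-execute the run; deterministic stages re-run
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import classify
from .classify import LabeledDataset, TrainConfig, predict, split_repeated, undersample
from .features import FEATURE_LENGTH, descriptor_manifest, extract_features
from .image_io import PreprocessConfig, load_image
from .metrics import (
    CLASSES,
    UndefinedMetricError,
    confusion,
    roc_auc,
    scalar_metrics,
)


def _package_version() -> str:
    try:
        return version("emaclass")
    except PackageNotFoundError:
        return "unknown"


def _digest_paths(paths: list[str]) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(str(p).encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def run_manifest(stage: str, params: dict, inputs: list[str] | None = None) -> dict:
    return {
        "stage": stage,
        "package_version": _package_version(),
        "params": params,
        "input_digest": _digest_paths(inputs or []),
        "n_inputs": len(inputs or []),
    }


def cmd_extract(
    manifest_csv: str | Path,
    out_features_csv: str | Path,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> pd.DataFrame:
    """Extract one descriptor row per image listed in a `path,label` manifest.

    All images must share dimensions; any unreadable image aborts the run
    with the offending path named, and no output file is written.  A sidecar
    JSON manifest recording the descriptor parameters is written next to the
    feature CSV.
    """
    manifest_csv = Path(manifest_csv)
    table = pd.read_csv(manifest_csv)
    for col in ("path", "label"):
        if col not in table.columns:
            raise ValueError(f"manifest {manifest_csv} lacks required column {col!r}")
    if len(table) == 0:
        raise ValueError(f"manifest {manifest_csv} lists no images")
    bad = sorted(set(table["label"]) - set(CLASSES))
    if bad:
        raise ValueError(f"manifest contains unknown labels {bad}")

    rows = []
    shape = None
    for path, label in zip(table["path"], table["label"]):
        p = Path(path)
        if not p.is_absolute():
            p = manifest_csv.parent / p
        img = load_image(p)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"image dimensions differ: {path} is {img.shape}, expected {shape}"
            )
        rows.append((str(path), label, extract_features(img, cfg)))

    cols = [f"f{i}" for i in range(FEATURE_LENGTH)]
    df = pd.DataFrame([r[2] for r in rows], columns=cols)
    df.insert(0, "label", [r[1] for r in rows])
    df.insert(0, "path", [r[0] for r in rows])
    out = Path(out_features_csv)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.12g")
    side = run_manifest(
        "extract", descriptor_manifest(cfg), list(table["path"].astype(str))
    )
    Path(str(out) + ".manifest.json").write_text(json.dumps(side, indent=2))
    return df


def load_features_csv(features_csv: str | Path) -> LabeledDataset:
    df = pd.read_csv(features_csv)
    missing = [c for c in ("label",) if c not in df.columns]
    if missing:
        raise ValueError(f"features CSV lacks required column(s) {missing}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not feat_cols:
        raise ValueError("features CSV contains no feature columns f0..fN")
    feat_cols = sorted(feat_cols, key=lambda c: int(c[1:]))
    return LabeledDataset(
        df[feat_cols].to_numpy(dtype=np.float64),
        df["label"].to_numpy(dtype=object),
    )


def evaluate_protocol(
    ds: LabeledDataset,
    cfg: TrainConfig,
    positive_class: str = "I",
    undersample_negatives: bool = False,
) -> dict:
    """Repeated stratified 70/30 splits; pooled held-out metrics.

    Trains one model per repeat, pools the held-out predictions across
    repeats into a single confusion matrix, and reports scalar metrics,
    per-class one-vs-all AUCs from the pooled scores, per-repeat accuracies
    (mean and SD) and mean per-image inference time (informational only).
    """
    notes = {}
    if undersample_negatives:
        before = ds.class_counts
        ds = undersample(ds, seed=cfg.seed)
        notes["undersampling"] = {"before": before, "after": ds.class_counts}

    splits = split_repeated(ds, cfg)
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_scores: list[np.ndarray] = []
    per_repeat_acc: list[float] = []
    infer_times: list[float] = []
    for tr, te in splits:
        model = classify.train(ds.subset(tr), cfg)
        t0 = time.perf_counter()
        pred, scores = predict(model, ds.features[te])
        infer_times.append((time.perf_counter() - t0) / len(te))
        pooled_true.extend(ds.labels[te])
        pooled_pred.extend(pred)
        pooled_scores.append(scores)
        per_repeat_acc.append(float(np.mean(pred == ds.labels[te])))

    cm = confusion(pooled_true, pooled_pred)
    report = scalar_metrics(cm, positive_class=positive_class)
    S = np.vstack(pooled_scores)
    truth = np.asarray(pooled_true, dtype=object)
    auc: dict[str, float | None] = {}
    for j, c in enumerate(CLASSES):
        try:
            auc[c] = roc_auc(S[:, j], truth == c)
        except UndefinedMetricError:
            auc[c] = None
            report.flags.append(f"auc.{c}")
    report.auc_per_class = auc
    counts = ds.class_counts
    from .metrics import class_shares

    present_total = sum(counts.values())
    report.class_shares = dict(
        zip(CLASSES, class_shares([counts[c] for c in CLASSES]))
    ) if present_total else {}

    return {
        "confusion_matrix": cm.tolist(),
        "class_order": list(CLASSES),
        "metrics": report.to_dict(),
        "per_repeat_accuracy": {
            "values": per_repeat_acc,
            "mean": float(np.mean(per_repeat_acc)),
            "sd": float(np.std(per_repeat_acc, ddof=1)) if len(per_repeat_acc) > 1 else 0.0,
        },
        "mean_inference_time_per_image_s": float(np.mean(infer_times)),
        "n_pooled_predictions": len(pooled_true),
        "notes": notes,
        "pooled_scores": S,
        "pooled_true": truth,
    }


def cmd_train_eval(
    features_csv: str | Path,
    cfg: TrainConfig,
    out_model: str | Path | None = None,
    out_report: str | Path | None = None,
    positive_class: str = "I",
    undersample_negatives: bool = False,
) -> tuple[classify.TrainedModel, dict]:
    """Full train-and-evaluate stage on a feature CSV.

    Runs the repeated-split evaluation protocol, then fits a final model on
    the complete (optionally under-sampled) dataset for deployment.  The
    model archive embeds the TrainConfig, descriptor digest and class order;
    the JSON report carries the metrics and a run manifest.
    """
    t0 = time.perf_counter()
    ds = load_features_csv(features_csv)
    result = evaluate_protocol(
        ds, cfg, positive_class=positive_class,
        undersample_negatives=undersample_negatives,
    )
    result.pop("pooled_scores")
    result.pop("pooled_true")

    fit_ds = undersample(ds, seed=cfg.seed) if undersample_negatives else ds
    final_model = classify.train(fit_ds, cfg)

    result["manifest"] = run_manifest(
        "train_eval",
        {
            "train_config": asdict(cfg),
            "positive_class": positive_class,
            "undersample": undersample_negatives,
            "feature_config_digest": final_model.feature_config_digest,
        },
        [str(features_csv)],
    )
    result["wall_time_s"] = time.perf_counter() - t0

    if out_model is not None:
        payload = {
            "model": final_model,
            "train_config": asdict(cfg),
            "class_order": list(CLASSES),
            "feature_config_digest": final_model.feature_config_digest,
        }
        Path(out_model).parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(payload, out_model)
    if out_report is not None:
        Path(out_report).parent.mkdir(parents=True, exist_ok=True)
        Path(out_report).write_text(json.dumps(result, indent=2))
    return final_model, result


def load_model(path: str | Path) -> classify.TrainedModel:
    payload = joblib.load(path)
    return payload["model"]
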