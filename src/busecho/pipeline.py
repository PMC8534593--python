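"""End-to-end orchestration of the classification and segmentation flows.

Two pipelines, each fully determined by a :class:`RunConfig` and its single
global seed (stage seeds are derived from it):

* classification: generate/load phantoms -> histogram features -> four
  classical classifiers + the CNN classifier -> confusion matrices and a
  five-row comparison table (model, auc, error, accuracy);
* segmentation: generate/load phantoms -> train the pixel CNN -> predict
  probability maps -> morphological refinement -> per-image ROC/AUC and
  lesion reports.

Outputs for a run are written under ``out_dir/run-<confighash>/`` so that
results from different configurations can never silently mix; a rerun with
the same config and seed overwrites the same directory with byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from busecho import classical, cnn, dataio, metrics, phantom, postmorph
from busecho.features_histogram import compute_histogram, extract_features, fit_four_gaussians

logger = logging.getLogger(__name__)

_STAGES = ("generate", "split", "features", "train", "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    out_dir: str = "runs"
    n_per_class: int = 20
    image_size: tuple[int, int] = (256, 256)
    split_ratio: float = 0.7
    feature_scheme: str = "means"
    fit_restarts: int = 3
    classifier_kinds: tuple[str, ...] = ("dt", "knn", "svm", "nb")
    cnn_iterations: int = 200
    cnn_batch_size: int = 16
    cnn_learning_rate: float = 1e-3
    seg_iterations: int = 150
    seg_threshold: float = 0.5
    morph_radius: int = 5
    morph_min_size: int = 20
    auc_cutoff: float = 0.6
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Derive a deterministic per-stage seed (< 2**31) from the global one."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(_STAGES.index(stage),))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("image_size", "classifier_kinds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def run_dir(self) -> Path:
        return Path(self.out_dir) / f"run-{self.config_hash()}"


def _prepare_dataset(cfg: RunConfig) -> tuple[pd.DataFrame, Path]:
    data_dir = cfg.run_dir() / "data"
    manifest = phantom.generate_dataset(cfg.n_per_class, cfg.stage_seed("generate"),
                                        data_dir, image_size=cfg.image_size)
    manifest = dataio.split_dataset(manifest, ratio=cfg.split_ratio,
                                    seed=cfg.stage_seed("split"))
    dataio.save_manifest(manifest, data_dir / "manifest.csv")
    return manifest, data_dir


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def compute_feature_table(manifest: pd.DataFrame, data_dir: Path,
                          scheme: str = "means", seed: int = 0,
                          n_restarts: int = 3) -> pd.DataFrame:
    """Histogram-model features for every image in a manifest."""
    rows = []
    for _, rec in manifest.iterrows():
        img = dataio.load_image(data_dir / rec["file"])
        model = fit_four_gaussians(compute_histogram(img), seed=seed,
                                   n_restarts=n_restarts)
        feats = extract_features(model, scheme)
        rows.append({"file": rec["file"], **{f"f{i + 1}": v for i, v in enumerate(feats)},
                     "residual": model.residual, "converged": model.converged})
    return pd.DataFrame(rows)


def run_classification_pipeline(cfg: RunConfig) -> dict:
    """Features -> 4 classical classifiers + CNN -> metrics table.

    Returns a report dict with the run directory, the metrics table (one
    row per model: auc, error, accuracy on the test split) and per-model
    confusion matrices; all tables are also written as CSV.
    """
    run_dir = cfg.run_dir()
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))

    manifest, data_dir = _prepare_dataset(cfg)
    feat_seed = cfg.stage_seed("features")
    features = compute_feature_table(manifest, data_dir, cfg.feature_scheme,
                                     seed=feat_seed, n_restarts=cfg.fit_restarts)
    _write_csv(features, run_dir / "features.csv")

    merged = manifest.merge(features, on="file")
    feat_cols = [c for c in features.columns
                 if c.startswith("f") and c[1:].isdigit()]
    is_train = merged["split"] == "train"
    X_train = merged.loc[is_train, feat_cols].to_numpy(float)
    y_train = merged.loc[is_train, "class"].to_numpy(int)
    X_test = merged.loc[~is_train, feat_cols].to_numpy(float)
    y_test = merged.loc[~is_train, "class"].to_numpy(int)

    train_seed = cfg.stage_seed("train")
    table_rows = []
    confusions: dict[str, classical.ConfusionMatrix] = {}

    for kind in cfg.classifier_kinds:
        spec = classical.ClassifierSpec(kind=kind, seed=train_seed)
        model = classical.train(spec, X_train, y_train)
        cm = classical.evaluate(model, X_test, y_test)
        confusions[kind] = cm
        scores = classical.predict_proba(model, X_test)
        auc = _macro_ovr_auc(scores, y_test, model.classes)
        table_rows.append({"model": kind, "auc": auc,
                           "error": 1.0 - cm.accuracy, "accuracy": cm.accuracy})
        _write_confusion(cm, run_dir / f"confusion_{kind}.csv")

    # CNN classifier on raw images
    net_cfg = cnn.NetConfig(task="classify", image_size=cfg.image_size,
                            iterations=cfg.cnn_iterations,
                            batch_size=cfg.cnn_batch_size,
                            learning_rate=cfg.cnn_learning_rate, seed=train_seed)
    net = cnn.build_classifier(net_cfg)
    train_imgs = np.stack([dataio.load_image(data_dir / f)
                           for f in merged.loc[is_train, "file"]])
    test_imgs = np.stack([dataio.load_image(data_dir / f)
                          for f in merged.loc[~is_train, "file"]])
    net, trace = cnn.train_classifier(net, train_imgs, y_train)
    probs = cnn.predict_proba(net, test_imgs)
    y_pred = probs.argmax(axis=1)
    classes = np.arange(net_cfg.n_classes)
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(y_test, y_pred):
        counts[t, p] += 1
    cm = classical.ConfusionMatrix(counts=counts, classes=classes)
    confusions["cnn"] = cm
    auc = _macro_ovr_auc(probs, y_test, classes)
    table_rows.append({"model": "cnn", "auc": auc,
                       "error": 1.0 - cm.accuracy, "accuracy": cm.accuracy})
    _write_confusion(cm, run_dir / "confusion_cnn.csv")
    pd.DataFrame({"iteration": np.arange(1, len(trace) + 1),
                  "loss": trace.loss, "accuracy": trace.accuracy}).pipe(
        _write_csv, run_dir / "cnn_train_trace.csv")

    metrics_table = pd.DataFrame(table_rows)
    _write_csv(metrics_table, run_dir / "metrics.csv")
    return {"run_dir": run_dir, "metrics": metrics_table, "confusions": confusions,
            "manifest": manifest}


def _macro_ovr_auc(scores: np.ndarray, y_true: np.ndarray,
                   classes: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC over the classes present in truth."""
    aucs = []
    for i, c in enumerate(classes):
        truth = np.asarray(y_true) == c
        if truth.any() and not truth.all():
            aucs.append(metrics.roc_curve(scores[:, i], truth).auc)
    return float(np.mean(aucs))


def _write_confusion(cm: classical.ConfusionMatrix, path: Path) -> None:
    df = pd.DataFrame(cm.counts,
                      index=[f"true_{c}" for c in cm.classes],
                      columns=[f"pred_{c}" for c in cm.classes])
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)


def run_segmentation_pipeline(cfg: RunConfig, manifest: pd.DataFrame | None = None,
                              data_dir: Path | None = None) -> dict:
    """Train the pixel CNN, refine masks, and score per-image ROC/AUC.

    By default a phantom dataset is generated from the config; an existing
    split ``manifest`` plus its ``data_dir`` may be supplied instead.
    Returns a report with per-image AUCs, the fraction above
    ``cfg.auc_cutoff``, lesion reports, and centroid errors against the
    generator's truth; artifacts are written under the run directory.
    """
    run_dir = cfg.run_dir()
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))

    if manifest is None:
        manifest, data_dir = _prepare_dataset(cfg)
    elif data_dir is None:
        raise ValueError("data_dir must accompany an explicit manifest")
    data_dir = Path(data_dir)
    lesional = manifest[manifest["class"] != phantom.NORMAL].reset_index(drop=True)
    for _, rec in lesional.iterrows():
        if not (data_dir / rec["mask_file"]).exists():
            raise FileNotFoundError(f"missing mask for {rec['file']}: {rec['mask_file']}")

    train_rows = lesional[lesional["split"] == "train"]
    test_rows = lesional[lesional["split"] == "test"]
    load = lambda col, rows: np.stack([dataio.load_image(data_dir / f)
                                       for f in rows[col]])
    net_cfg = cnn.NetConfig(task="segment", image_size=cfg.image_size,
                            conv_channels=(8, 16), iterations=cfg.seg_iterations,
                            batch_size=min(8, len(train_rows)),
                            learning_rate=cfg.cnn_learning_rate,
                            seed=cfg.stage_seed("train"))
    net = cnn.build_segmenter(net_cfg)
    net, trace = cnn.train_segmenter(net, load("file", train_rows),
                                     load("mask_file", train_rows))

    records, reports = [], {}
    for _, rec in test_rows.iterrows():
        img = dataio.load_image(data_dir / rec["file"])
        gt = dataio.load_image(data_dir / rec["mask_file"])
        prob_map, raw_mask = cnn.predict_mask(net, img, threshold=cfg.seg_threshold)
        refined = postmorph.morphological_refine(raw_mask, radius=cfg.morph_radius,
                                                 min_size=cfg.morph_min_size)
        report = postmorph.lesion_report(refined, raw_mask=raw_mask)
        try:
            auc = metrics.per_image_auc(prob_map, gt)
        except ValueError as exc:
            logger.warning("excluding %s from AUC summary: %s", rec["file"], exc)
            auc = np.nan
        if report.present:
            centroid_err = float(np.hypot(report.centroid[0] - rec["lesion_row"],
                                          report.centroid[1] - rec["lesion_col"]))
        else:
            centroid_err = np.nan
        records.append({"file": rec["file"], "auc": auc,
                        "centroid_error_px": centroid_err,
                        "area_px": report.area_px if report.present else 0,
                        "true_area_px": rec["lesion_area_px"]})
        reports[rec["file"]] = report
        report.to_json(run_dir / f"lesion_{Path(rec['file']).stem}.json")

    per_image = pd.DataFrame(records)
    _write_csv(per_image, run_dir / "per_image_auc.csv")
    valid = per_image["auc"].dropna()
    summary = {
        "n_test": len(per_image),
        "median_auc": float(valid.median()),
        "frac_auc_above_cutoff": metrics.auc_summary(valid, cfg.auc_cutoff),
        "median_centroid_error_px": float(per_image["centroid_error_px"].median()),
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"run_dir": run_dir, "per_image": per_image, "summary": summary,
            "reports": reports, "trace": trace, "manifest": manifest, "net": net}
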