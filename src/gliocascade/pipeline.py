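"""End-to-end cascade: simulate -> preprocess -> segment -> ROI -> classify.

Functions here are the library behind the command-line interface; they
never read ground truth during inference (``run_cascade`` takes only a
scan), and every entry point is reproducible from its (config, seed)
pair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import CNNClassifier, extract_roi
from .errors import ConfigError, DataError
from .io_volumes import (BinaryMask, LabelVolume, read_case, region_mask, write_labels)
from .metrics import FoldReport, MetricsRecord, kfold_evaluate, make_split
from .preprocess import PreprocessConfig, preprocess_case
from .segmenter import UNetSegmenter

log = logging.getLogger("gliocascade")


@dataclasses.dataclass
class RunConfig:
    """One YAML document configuring every stage; flags override fields."""

    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    region: str = "complete"
    protocol: str = "split_70_15_15"  # or "kfold_10"
    k: int = 10
    target_shape: tuple = (32, 32, 32)
    normalize: str = "zscore"
    # segmenter
    depth: int = 4
    encoder_filters: tuple = (8, 16, 32, 64)
    upsample_mode: str = "nearest"
    seg_epochs: int = 30
    # classifier
    clf_filters: tuple = (8, 16, 32, 64, 128)
    clf_epochs: int = 30
    # shared optimization (reference recipe)
    learning_rate: float = 1e-3
    batch_size: int = 16
    l2_lambda: float = 4e-4
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        flat = {}
        for section in doc.values() if all(isinstance(v, dict) for v in doc.values()) \
                else [doc]:
            flat.update(section)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(flat) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def pre_cfg(self) -> PreprocessConfig:
        return PreprocessConfig(target_shape=tuple(self.target_shape),
                                normalize=self.normalize)

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_manifest(data_dir) -> pd.DataFrame:
    manifest = Path(data_dir) / "manifest.csv"
    if not manifest.exists():
        raise DataError(f"no manifest.csv under {data_dir}")
    return pd.read_csv(manifest)


def load_cases(data_dir, with_truth: bool = True):
    """Yield (case_id, grade, scan, truth) for every manifest entry."""
    df = load_manifest(data_dir)
    out = []
    for _, row in df.iterrows():
        scan, truth = read_case(Path(data_dir) / row["case_id"], with_truth=with_truth)
        out.append((row["case_id"], row["grade"], scan, truth))
    return out


def prepare_segmentation_data(cases, cfg: RunConfig):
    """Cases -> (X, y): preprocessed tensors and binary region targets."""
    pre = cfg.pre_cfg()
    xs, ys = [], []
    for _, _, scan, truth in cases:
        tensor, labels = preprocess_case(scan, truth, pre)
        xs.append(tensor)
        ys.append(region_mask(labels, cfg.region).mask)
    return np.stack(xs), np.stack(ys)


def prepare_roi_data(cases, cfg: RunConfig, segmenter: UNetSegmenter = None):
    """Cases -> (roi tensors, grade labels, empty flags).

    Masks come from the trained segmenter when given, else from ground
    truth (training-time default).
    """
    pre = cfg.pre_cfg()
    xs, ys, empties = [], [], []
    for _, grade, scan, truth in cases:
        tensor, labels = preprocess_case(scan, truth, pre)
        if segmenter is not None:
            mask = segmenter.predict(tensor[None])[0]
        else:
            if labels is None:
                raise DataError("no truth available for ROI extraction")
            mask = region_mask(labels, cfg.region).mask
        roi = extract_roi(tensor, mask)
        xs.append(roi.tensor)
        ys.append(grade)
        empties.append(roi.empty)
    return np.stack(xs), np.asarray(ys), np.asarray(empties)


def train_segmenter_on(cases, cfg: RunConfig) -> UNetSegmenter:
    X, y = prepare_segmentation_data(cases, cfg)
    est = UNetSegmenter(depth=cfg.depth, encoder_filters=tuple(cfg.encoder_filters),
                        upsample_mode=cfg.upsample_mode,
                        learning_rate=cfg.learning_rate, epochs=cfg.seg_epochs,
                        batch_size=cfg.batch_size, l2_lambda=cfg.l2_lambda,
                        threshold=cfg.threshold, random_state=cfg.seed)
    return est.fit(X, y)


def train_classifier_on(cases, cfg: RunConfig,
                        segmenter: UNetSegmenter = None) -> CNNClassifier:
    X, y, _ = prepare_roi_data(cases, cfg, segmenter=segmenter)
    est = CNNClassifier(filters=tuple(cfg.clf_filters),
                        learning_rate=cfg.learning_rate, epochs=cfg.clf_epochs,
                        batch_size=cfg.batch_size, l2_lambda=cfg.l2_lambda,
                        random_state=cfg.seed)
    return est.fit(X, y)


def run_cascade(scan, segmenter: UNetSegmenter, classifier: CNNClassifier = None,
                cfg: RunConfig = None):
    """Inference on one scan; never touches ground truth.

    Returns a dict with the probability map, binary mask, ROI empty
    flag and (when a classifier is given) class probabilities.
    """
    cfg = cfg or RunConfig()
    tensor, _ = preprocess_case(scan, None, cfg.pre_cfg())
    proba = segmenter.predict_proba(tensor[None])[0]
    mask = (proba >= cfg.threshold).astype(np.uint8)
    result = {"proba": proba, "mask": BinaryMask(mask=mask, region=cfg.region),
              "tensor": tensor}
    roi = extract_roi(tensor, mask)
    result["roi_empty"] = roi.empty
    if classifier is not None:
        probs = classifier.predict_proba(roi.tensor[None])[0]
        result["class_proba"] = {str(c): float(p)
                                 for c, p in zip(classifier.classes_, probs)}
    return result


def cascade_case_outputs(case_dir, segmenter, classifier, cfg: RunConfig, out_dir):
    """Run the cascade on one stored case and write its artifacts.

    Writes ``predicted_mask.mha``, ``class_proba.json`` and, when truth
    is available on disk, a ``metrics.csv`` row comparing the predicted
    mask against the matching truth region at the working resolution.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan, _ = read_case(case_dir, with_truth=False)
    result = run_cascade(scan, segmenter, classifier, cfg)
    write_labels(LabelVolume(labels=result["mask"].mask.astype(np.int16)),
                 out_dir / "predicted_mask.mha")
    if "class_proba" in result:
        (out_dir / "class_proba.json").write_text(
            json.dumps({"class_proba": result["class_proba"],
                        "roi_empty": bool(result["roi_empty"])}, indent=2,
                       sort_keys=True))
    truth_path = Path(case_dir) / "truth.mha"
    if truth_path.exists():
        from .io_volumes import read_labels
        from .preprocess import resample
        truth = read_labels(truth_path)
        small = LabelVolume(labels=resample(truth.labels, cfg.target_shape, kind="label"))
        rec = MetricsRecord.from_masks(result["mask"], region_mask(small, cfg.region))
        pd.DataFrame([dataclasses.asdict(rec)]).to_csv(out_dir / "metrics.csv",
                                                       index=False)
    return result


def evaluate_kfold(cases, cfg: RunConfig) -> dict:
    """k-fold cross-validation of the full cascade, per grade.

    Each fold trains a segmenter on the training cases and evaluates
    voxel-level Dice/sensitivity/accuracy of the predicted region masks
    on the held-out cases; reports are returned per grade plus pooled.
    """

    def train_fn(train_cases):
        return train_segmenter_on(train_cases, cfg)

    def eval_fn(model, test_cases):
        X, y = prepare_segmentation_data(test_cases, cfg)
        pred = model.predict(X)
        return MetricsRecord.from_masks(pred, y)

    report = kfold_evaluate(cases, train_fn, eval_fn, k=cfg.k, seed=cfg.seed)
    return {"all": report}


def report_from_fold_csv(path) -> FoldReport:
    """Aggregate an existing per-fold CSV (percent columns dice,
    sensitivity, accuracy) into a report with an Avg row."""
    df = pd.read_csv(path)
    needed = {"dice", "sensitivity", "accuracy"}
    if not needed.issubset(df.columns):
        raise DataError(f"fold CSV must have columns {sorted(needed)}")
    df = df[~df.iloc[:, 0].astype(str).str.startswith("Avg")]
    return FoldReport.from_percent_columns(df["dice"].astype(float),
                                           df["sensitivity"].astype(float),
                                           df["accuracy"].astype(float))


def save_montage(tensor: np.ndarray, path, n_slices: int = 4):
    """Minimal axial slice-montage export (plumbing, not analysis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tensor = np.asarray(tensor)
    z = np.linspace(0, tensor.shape[-1] - 1, n_slices).astype(int)
    fig, axes = plt.subplots(tensor.shape[0], n_slices,
                             figsize=(2 * n_slices, 2 * tensor.shape[0]))
    axes = np.atleast_2d(axes)
    for c in range(tensor.shape[0]):
        for i, zi in enumerate(z):
            axes[c, i].imshow(tensor[c, :, :, zi].T, cmap="gray", origin="lower")
            axes[c, i].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=72)
    plt.close(fig)
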