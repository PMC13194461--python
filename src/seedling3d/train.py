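"""Training loop and semantic-segmentation metric suite.

Training follows the study protocol: Adam (lr 1e-3, weight decay 1e-4),
step decay to 0.5x every 10 epochs, batch size 16, scenes uniformly
resampled to 2049 points, unweighted cross-entropy.  Evaluation aggregates
confusion counts over all scenes of a split before computing metrics once
(micro-averaging), so it is invariant to scene order and concatenation.

With background purification applied upstream, only the stem and leaf
classes occur; classes absent from both prediction and truth are excluded
from the mIoU average (0/0 metrics reported as 0).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .autograd import Adam
from .cloud import LabeledPointCloud
from .network import (
    ModelConfig,
    ScenePlan,
    SegmentationModel,
    StageConfig,
    build_model,
    build_scene_plan,
    cross_entropy,
    stack_plans,
)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (study defaults)."""

    epochs: int = 150
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 1e-4
    lr_step: int = 10          # epochs between decays
    lr_factor: float = 0.5
    n_points: int = 2049
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if min(self.epochs, self.batch_size, self.lr_step, self.n_points) <= 0:
            raise ValueError("epochs, batch, lr_step and n_points must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr decay factor must lie in (0, 1)")
        return self


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

def resample_points(cloud: LabeledPointCloud, n: int = 2049,
                    seed: int = 0) -> LabeledPointCloud:
    """Uniformly resample to exactly ``n`` points (labels follow points).

    Without replacement when the scene is large enough, with replacement
    otherwise.
    """
    if cloud.n_points < 1:
        raise ValueError("cannot resample an empty cloud")
    rng = np.random.default_rng(seed)
    replace = cloud.n_points < n
    idx = rng.choice(cloud.n_points, size=n, replace=replace)
    return cloud.select(idx)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN point counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp.sum() + self.fn.sum())

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def confusion(pred, true, n_classes: int = 3) -> ConfusionCounts:
    """Exact per-class counts from two equal-length label vectors."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        tp[c] = int(np.sum((pred == c) & (true == c)))
        fp[c] = int(np.sum((pred == c) & (true != c)))
        fn[c] = int(np.sum((pred != c) & (true == c)))
    return ConfusionCounts(tp, fp, fn)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/IoU plus overall accuracy and mIoU."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    iou: np.ndarray
    overall_accuracy: float
    miou: float
    present: np.ndarray        # classes with TP+FP+FN > 0

    def to_frame(self, class_names=None) -> pd.DataFrame:
        n = len(self.precision)
        names = class_names or [str(c) for c in range(n)]
        return pd.DataFrame(
            {
                "class": names,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "iou": self.iou,
            }
        )


def _safe_div(num, den):
    den = np.asarray(den, dtype=np.float64)
    out = np.zeros_like(den)
    np.divide(num, den, out=out, where=den > 0)
    return out


def class_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Apply the precision/recall/F1/IoU formulas per class.

    Classes that occur in neither prediction nor truth are excluded from
    the mIoU average; their undefined per-class metrics are reported as 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    iou = _safe_div(tp, tp + fp + fn)
    present = (tp + fp + fn) > 0
    miou = float(iou[present].mean()) if present.any() else 0.0
    total = counts.total
    acc = float(tp.sum() / total) if total else 0.0
    return MetricsReport(precision, recall, f1, iou, acc, miou, present)


# ----------------------------------------------------------------------
# scene preparation
# ----------------------------------------------------------------------

@dataclass
class PreparedScene:
    """Resampled scene with its cached sampling pyramid."""

    features: np.ndarray
    labels: np.ndarray
    plan: ScenePlan


def prepare_scene(cloud: LabeledPointCloud, model: SegmentationModel,
                  n_points: int, seed: int) -> PreparedScene:
    sampled = resample_points(cloud, n_points, seed)
    feats = model.features_from_cloud(sampled.coords, sampled.normals,
                                      sampled.colors)
    plan = build_scene_plan(sampled.coords, model.config)
    return PreparedScene(feats, sampled.sem_label.copy(), plan)


def _forward_split(model, prepared, batch_size):
    """Predicted labels and mean loss over a list of prepared scenes."""
    losses, counts = [], None
    for start in range(0, len(prepared), batch_size):
        chunk = prepared[start:start + batch_size]
        plan = stack_plans([p.plan for p in chunk])
        feats = np.stack([p.features for p in chunk])
        labels = np.stack([p.labels for p in chunk])
        logits = model.forward(plan, feats)
        losses.append(float(cross_entropy(logits, labels).data))
        pred = np.argmax(logits.data, axis=-1)
        c = confusion(pred, labels, model.config.n_classes)
        counts = c if counts is None else counts + c
    return float(np.mean(losses)), counts


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_scenes,
    val_scenes,
    verbose: bool = False,
):
    """Train a segmentation model; returns ``(model, history frame)``.

    The best-validation-mIoU weights are restored before returning.  The
    run is fully deterministic given the two configs and the scene lists.
    """
    train_config = train_config.validate()
    if not train_scenes or not val_scenes:
        raise ValueError("train and validation splits must be non-empty")
    model = build_model(model_config)
    rng = np.random.default_rng(train_config.seed)
    prep_train = [
        prepare_scene(c, model, train_config.n_points, train_config.seed + i)
        for i, c in enumerate(train_scenes)
    ]
    prep_val = [
        prepare_scene(c, model, train_config.n_points, 900_000 + i)
        for i, c in enumerate(val_scenes)
    ]
    optimizer = Adam(model.parameters(), lr=train_config.lr,
                     weight_decay=train_config.weight_decay)
    history, best = [], (-1.0, None)
    for epoch in range(train_config.epochs):
        lr = train_config.lr * train_config.lr_factor ** (epoch // train_config.lr_step)
        optimizer.lr = lr
        order = rng.permutation(len(prep_train))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            chunk = [prep_train[i] for i in order[start:start + train_config.batch_size]]
            plan = stack_plans([p.plan for p in chunk])
            feats = np.stack([p.features for p in chunk])
            labels = np.stack([p.labels for p in chunk])
            loss = cross_entropy(model.forward(plan, feats), labels)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={value}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        val_loss, val_counts = _forward_split(model, prep_val,
                                              train_config.batch_size)
        report = class_metrics(val_counts)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_acc": report.overall_accuracy,
                "val_miou": report.miou,
            }
        )
        if report.miou > best[0]:
            best = (report.miou, [p.data.copy() for p in model.parameters()])
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr:.2e} "
                f"train {history[-1]['train_loss']:.4f} "
                f"val {val_loss:.4f} acc {report.overall_accuracy:.4f} "
                f"mIoU {report.miou:.4f}"
            )
    if best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data = data
    return model, pd.DataFrame(history)


def evaluate(model: SegmentationModel, scenes, n_points: int = 2049,
             batch_size: int = 16, seed: int = 0) -> MetricsReport:
    """Micro-averaged metrics over a split (confusion summed over scenes)."""
    if not scenes:
        raise ValueError("cannot evaluate an empty split")
    prepared = [
        prepare_scene(c, model, n_points, seed + i) for i, c in enumerate(scenes)
    ]
    _, counts = _forward_split(model, prepared, batch_size)
    return class_metrics(counts)


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path, extra=None) -> None:
    cfg = asdict(model.config)
    cfg["stages"] = [asdict(s) for s in model.config.stages]
    arrays = {f"w{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(
        path,
        config=json.dumps(cfg),
        extra=json.dumps(extra or {}),
        **arrays,
    )


def load_checkpoint(path) -> SegmentationModel:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    cfg["stages"] = tuple(StageConfig(**s) for s in cfg["stages"])
    cfg["fp_channels"] = tuple(cfg["fp_channels"])
    model = build_model(ModelConfig(**cfg))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"w{i}"]
    return model
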