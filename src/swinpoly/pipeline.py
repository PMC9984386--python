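"""End-to-end orchestration: train → checkpoint → evaluate → explain.

Training follows the published recipe: Xavier-initialized weights, Adam with
β₁ = 0.9, learning rate annealed (cosine by default) from 2e-4 down to 1e-5,
batch size 32, Poly-1 loss with ε₁ = 2 and optional inverse-frequency class
weighting, and the model at the *last* epoch kept — no best-validation
selection.  One seed drives weight init, shuffling and augmentation, giving
bit-reproducible runs on a single machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AugmentationPolicy, DatasetManifest, augment, class_weights, preprocess
from .losses import cross_entropy, poly1_loss
from .metrics import MetricsReport, report, roc_points
from .model import SwinClassifier, SwinConfig, load_checkpoint, save_checkpoint
from .nn import Adam, cosine_lr
from .scorecam import SaliencyMap, normalize_map, overlay_heatmap, scorecam_map

__all__ = ["TrainConfig", "RunLog", "TrainingDiverged",
           "train", "evaluate", "explain"]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    model: SwinConfig = field(default_factory=SwinConfig)
    loss: str = "poly1"                  # "poly1" | "cross_entropy"
    epsilon1: float = 2.0
    class_weighting: str = "inverse_freq"  # "inverse_freq" | "none"
    lr_init: float = 2e-4
    lr_final: float = 1e-5
    lr_schedule: str = "cosine"          # "cosine" | "step"
    beta1: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)

    def __post_init__(self):
        if self.loss not in ("poly1", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.class_weighting not in ("inverse_freq", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.lr_schedule not in ("cosine", "step"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must not exceed lr_init")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class RunLog:
    """Per-epoch training trace."""

    rows: pd.DataFrame   # epoch, lr, train_loss, train_accuracy, val_accuracy, seconds
    config: dict
    seed: int

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    if cfg.lr_schedule == "cosine":
        return cosine_lr(epoch, cfg.epochs, cfg.lr_init, cfg.lr_final)
    # step: decade-style drop at 50% and 80% of the run, floored at lr_final
    frac = epoch / max(cfg.epochs - 1, 1)
    lr = cfg.lr_init * (0.1 if frac >= 0.5 else 1.0) * (0.1 if frac >= 0.8 else 1.0)
    return max(lr, cfg.lr_final)


def _load_split(manifest: DatasetManifest, split: str,
                model_cfg: SwinConfig) -> tuple[np.ndarray, np.ndarray]:
    paths, labels = manifest.paths_and_labels(split)
    images = np.stack([preprocess(p, size=model_cfg.input_size,
                                  in_channels=model_cfg.in_channels)
                       for p in paths]) if paths else \
        np.empty((0, model_cfg.input_size, model_cfg.input_size,
                  model_cfg.in_channels), dtype=np.float32)
    return images, np.asarray(labels)


def _batch_predict(model: SwinClassifier, images: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
    probs = [model.predict_proba(images[i:i + batch_size])
             for i in range(0, len(images), batch_size)]
    return np.concatenate(probs) if probs else np.empty((0, model.cfg.num_classes))


def train(cfg: TrainConfig, manifest: DatasetManifest,
          out_dir) -> tuple[Path, RunLog]:
    """Train on the manifest's train split and save the final-epoch model.

    Returns the checkpoint path and the per-epoch :class:`RunLog`; both are
    also written under ``out_dir`` (``checkpoint.npz``, ``runlog.csv``,
    ``run.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(manifest.class_names) != cfg.model.num_classes:
        raise ValueError(
            f"manifest has {len(manifest.class_names)} classes but the model "
            f"head expects {cfg.model.num_classes}")
    rng = np.random.default_rng(cfg.seed)
    model = SwinClassifier(cfg.model, rng=rng)
    optimizer = Adam(model.parameters(), lr=cfg.lr_init, beta1=cfg.beta1)
    weights = (class_weights(manifest) if cfg.class_weighting == "inverse_freq"
               else None)

    train_x, train_y = _load_split(manifest, "train", cfg.model)
    val_x, val_y = _load_split(manifest, "val", cfg.model)
    if not len(train_x):
        raise ValueError("manifest has no training images")

    rows = []
    for epoch in range(cfg.epochs):
        tic = time.perf_counter()
        optimizer.lr = _lr_at(cfg, epoch)
        order = rng.permutation(len(train_x))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.stack([augment(train_x[i], cfg.augmentation, rng)
                              for i in idx])
            targets = train_y[idx]
            logits = model(batch)
            if cfg.loss == "poly1":
                loss = poly1_loss(logits, targets, cfg.epsilon1, weights)
            else:
                loss = cross_entropy(logits, targets, weights)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}: "
                    f"{loss.data!r}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == targets).sum())
        val_acc = (float((_batch_predict(model, val_x, cfg.batch_size)
                          .argmax(axis=1) == val_y).mean())
                   if len(val_x) else np.nan)
        rows.append({"epoch": epoch, "lr": optimizer.lr,
                     "train_loss": float(np.mean(losses)),
                     "train_accuracy": correct / len(train_x),
                     "val_accuracy": val_acc,
                     "seconds": time.perf_counter() - tic})

    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt_path, model, manifest.class_names)
    log = RunLog(pd.DataFrame(rows), config=_config_snapshot(cfg), seed=cfg.seed)
    log.to_csv(out_dir / "runlog.csv")
    (out_dir / "run.json").write_text(json.dumps(
        {"config": log.config, "seed": cfg.seed}, indent=2))
    return ckpt_path, log


def _config_snapshot(cfg: TrainConfig) -> dict:
    d = {k: getattr(cfg, k) for k in
         ("loss", "epsilon1", "class_weighting", "lr_init", "lr_final",
          "lr_schedule", "beta1", "epochs", "batch_size", "seed")}
    d["model"] = cfg.model.to_dict()
    d["augmentation"] = {
        "rotation_degrees": cfg.augmentation.rotation_degrees,
        "mirror_probability": cfg.augmentation.mirror_probability,
        "flip_probability": cfg.augmentation.flip_probability,
    }
    return d


def evaluate(checkpoint, manifest: DatasetManifest, split: str = "test",
             out_dir=None) -> MetricsReport:
    """Argmax-of-softmax evaluation of a checkpoint on one manifest split."""
    model, classes = load_checkpoint(checkpoint)
    if classes is not None and list(classes) != list(manifest.class_names):
        raise ValueError(
            f"checkpoint classes {classes} do not match manifest classes "
            f"{manifest.class_names}")
    images, labels = _load_split(manifest, split, model.cfg)
    if not len(images):
        raise ValueError(f"manifest has no images in split {split!r}")
    probs = _batch_predict(model, images)
    preds = probs.argmax(axis=1)
    rep = report(labels, preds, probs, class_names=list(manifest.class_names))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "metrics.json").write_text(json.dumps(rep.to_dict(), indent=2))
        pd.DataFrame(rep.confusion, index=rep.class_names,
                     columns=rep.class_names).to_csv(out_dir / "confusion.csv")
        for k, cls in enumerate(rep.class_names):
            pd.DataFrame(roc_points(labels, probs[:, k], k),
                         columns=["fpr", "tpr", "threshold"]).to_csv(
                out_dir / f"roc_{cls}.csv", index=False)
    return rep


def explain(checkpoint, image_path, class_index: int | None = None,
            out_path=None) -> tuple[SaliencyMap, dict]:
    """Score-CAM explanation of one image; writes overlay PNG + JSON sidecar.

    When `class_index` is omitted, the predicted class is explained; the
    sidecar records which.
    """
    from PIL import Image as PILImage
    model, classes = load_checkpoint(checkpoint)
    image = preprocess(image_path, size=model.cfg.input_size,
                       in_channels=model.cfg.in_channels)
    probs = model.predict_proba(image[None])[0]
    sal = scorecam_map(model, image, class_index=class_index)
    sidecar = {
        "image": str(image_path),
        "explained_class_index": sal.class_index,
        "explained_class": (classes[sal.class_index] if classes else None),
        "class_was_requested": class_index is not None,
        "probabilities": {
            (classes[k] if classes else f"class_{k}"): float(p)
            for k, p in enumerate(probs)},
        "saliency": sal.values.tolist(),
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        rgb = overlay_heatmap(image, normalize_map(sal.values))
        PILImage.fromarray(rgb, mode="RGB").save(out_path)
        out_path.with_suffix(".json").write_text(json.dumps(sidecar))
    return sal, sidecar
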