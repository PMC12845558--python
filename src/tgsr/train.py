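"""Dataset augmentation, stratified splitting, training and macro metrics.

Augmentation follows the usual leaf-imaging recipe: horizontal/vertical
flips plus random brightness/contrast/saturation jitter.  Splitting is
stratified 7:2:1 per stage; the default mode splits *source* images before
augmentation so no derivative of a test image can leak into training (an
``after_augmentation`` mode that splits the augmented pool is available for
protocol comparisons).  Evaluation accumulates a 6x6 confusion matrix and
derives one-vs-rest (OvR) precision/recall/F1 per class with unweighted
macro averages.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .net import TGSRNet
from .nn import Adam
from .nn.tensor import Tensor, cross_entropy

__all__ = [
    "AugmentConfig", "TrainConfig", "MetricsReport", "TrainResult",
    "augment", "augment_dataset", "split_dataset", "load_images",
    "train", "evaluate", "macro_metrics",
]

# Channel statistics of large-scale natural-image pretraining corpora; the
# customary default for normalising RGB input to CNN classifiers.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

NUM_CLASSES = 6


@dataclass(frozen=True)
class AugmentConfig:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    color_jitter: bool = True
    brightness: tuple[float, float] = (0.8, 1.2)
    contrast: tuple[float, float] = (0.8, 1.2)
    saturation: tuple[float, float] = (0.8, 1.2)


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0
    split_ratio: tuple[float, float, float] = (0.7, 0.2, 0.1)
    split_mode: str = "before_augmentation"
    input_size: int = 224
    normalize_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalize_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError(f"split_ratio must sum to 1: {self.split_ratio}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.split_mode not in ("before_augmentation",
                                   "after_augmentation"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _jitter(img: np.ndarray, rng: np.random.Generator,
            cfg: AugmentConfig) -> np.ndarray:
    out = img.astype(np.float64)
    f_b = rng.uniform(*cfg.brightness)
    f_c = rng.uniform(*cfg.contrast)
    f_s = rng.uniform(*cfg.saturation)
    out = out * f_b
    mean = out.mean()
    out = mean + f_c * (out - mean)
    gray = out @ np.array([0.299, 0.587, 0.114])
    out = gray[..., None] + f_s * (out - gray[..., None])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(img: np.ndarray, ops_config: AugmentConfig | None = None,
            seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """Deterministic augmented copies of one image, as (tag, image) pairs."""
    cfg = ops_config or AugmentConfig()
    rng = np.random.default_rng(seed)
    out: list[tuple[str, np.ndarray]] = []
    if cfg.horizontal_flip:
        out.append(("hflip", img[:, ::-1].copy()))
    if cfg.vertical_flip:
        out.append(("vflip", img[::-1].copy()))
    if cfg.color_jitter:
        out.append(("jitter", _jitter(img, rng, cfg)))
    return out


def augment_dataset(manifest: list[tuple[str, int]], root,
                    ops_config: AugmentConfig | None = None,
                    seed: int = 0) -> list[tuple[str, int]]:
    """Write augmented copies next to the sources and return the expanded
    manifest.  Derivative files carry a ``__aug-<tag>`` suffix, which the
    leakage-safe split mode uses to group them with their source."""
    root = Path(root)
    rows = list(manifest)
    for i, (rel, stage) in enumerate(manifest):
        img = np.asarray(Image.open(root / rel).convert("RGB"))
        for tag, aug in augment(img, ops_config, seed=seed + i):
            p = Path(rel)
            rel_aug = str(p.with_name(f"{p.stem}__aug-{tag}{p.suffix}"))
            Image.fromarray(aug).save(root / rel_aug)
            rows.append((rel_aug, stage))
    return rows


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _source_key(path: str) -> str:
    stem = Path(path).stem
    return stem.split("__aug-")[0]


def split_dataset(manifest: list[tuple[str, int]], config: TrainConfig
                  ) -> tuple[list[tuple[str, int]], list[tuple[str, int]],
                             list[tuple[str, int]]]:
    """Stratified train/val/test partition of a manifest.

    ``before_augmentation`` mode groups rows sharing a source image (same
    stem before any ``__aug-`` suffix) into one unit so derivatives never
    straddle partitions; ``after_augmentation`` splits rows independently.
    """
    if not manifest:
        raise ValueError("manifest is empty")
    by_class: dict[int, list] = {}
    for row in manifest:
        by_class.setdefault(row[1], []).append(row)
    for stage, rows in by_class.items():
        if len(rows) < 10:
            warnings.warn(f"stage {stage} has only {len(rows)} samples; "
                          "the 7:2:1 split will be coarse", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    r_tr, r_va, _ = config.split_ratio
    parts: tuple[list, list, list] = ([], [], [])
    for stage in sorted(by_class):
        rows = by_class[stage]
        if config.split_mode == "before_augmentation":
            groups: dict[str, list] = {}
            for row in rows:
                groups.setdefault(_source_key(row[0]), []).append(row)
            units = [groups[k] for k in sorted(groups)]
        else:
            units = [[row] for row in rows]
        order = rng.permutation(len(units))
        n = len(units)
        n_tr = int(round(n * r_tr))
        n_va = int(round(n * r_va))
        n_va = min(n_va, n - n_tr)
        bounds = (n_tr, n_tr + n_va)
        for rank, idx in enumerate(order):
            dest = 0 if rank < bounds[0] else (1 if rank < bounds[1] else 2)
            parts[dest].extend(units[idx])
    return parts


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def load_images(manifest: list[tuple[str, int]], root, *,
                input_size: int = 224) -> tuple[np.ndarray, np.ndarray]:
    """Load and bilinearly resize a manifest; returns (uint8 NHWC, labels).

    Labels keep the 1-6 stage convention.
    """
    root = Path(root)
    images = np.empty((len(manifest), input_size, input_size, 3), np.uint8)
    labels = np.empty(len(manifest), dtype=np.int64)
    for i, (rel, stage) in enumerate(manifest):
        if not 1 <= stage <= NUM_CLASSES:
            raise ValueError(f"stage label {stage} outside 1-{NUM_CLASSES} "
                             f"for {rel}")
        img = Image.open(root / rel).convert("RGB")
        if img.size != (input_size, input_size):
            img = img.resize((input_size, input_size), Image.BILINEAR)
        images[i] = np.asarray(img)
        labels[i] = stage
    return images, labels


def _normalize(batch_u8: np.ndarray, config: TrainConfig) -> np.ndarray:
    """uint8 NHWC -> float32 NCHW, [0,1] scaling then standardisation."""
    x = batch_u8.astype(np.float32) / 255.0
    x -= np.asarray(config.normalize_mean, np.float32)
    x /= np.asarray(config.normalize_std, np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = 0.0
    best_state: dict | None = None


def _accuracy(net: TGSRNet, images: np.ndarray, labels: np.ndarray,
              config: TrainConfig) -> float:
    preds = []
    for i in range(0, len(images), config.batch_size):
        x = _normalize(images[i:i + config.batch_size], config)
        preds.append(net.predict(x, batch_size=config.batch_size))
    pred = np.concatenate(preds) + 1
    return float((pred == labels).mean())


def train(net: TGSRNet, train_manifest: list[tuple[str, int]],
          val_manifest: list[tuple[str, int]], config: TrainConfig,
          root, *, verbose: bool = True) -> TrainResult:
    """Adam / cross-entropy training with per-epoch validation.

    The checkpoint with the best validation accuracy is retained in
    ``TrainResult.best_state``.  Raises on an empty loader and on a
    non-finite loss (reporting the epoch).
    """
    if not train_manifest:
        raise ValueError("training manifest is empty")
    if not val_manifest:
        raise ValueError("validation manifest is empty")
    tr_images, tr_labels = load_images(train_manifest, root,
                                       input_size=config.input_size)
    va_images, va_labels = load_images(val_manifest, root,
                                       input_size=config.input_size)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    result = TrainResult()
    for epoch in range(config.epochs):
        net.train()
        order = rng.permutation(len(tr_images))
        losses = []
        t0 = time.time()
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            x = _normalize(tr_images[idx], config)
            y = tr_labels[idx] - 1
            net.zero_grad()
            loss = cross_entropy(net(Tensor(x)), y)
            if not np.isfinite(loss.data).all():
                raise RuntimeError(f"non-finite loss at epoch {epoch + 1}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_acc = _accuracy(net, va_images, va_labels, config)
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                 "val_accuracy": val_acc,
                 "seconds": round(time.time() - t0, 2)}
        result.history.append(entry)
        if verbose:
            print(f"epoch {entry['epoch']:3d}  loss {entry['train_loss']:.4f}"
                  f"  val_acc {val_acc:.3f}  ({entry['seconds']}s)")
        if val_acc >= result.best_val_accuracy:
            result.best_val_accuracy = val_acc
            result.best_epoch = epoch + 1
            result.best_state = copy.deepcopy(net.state_dict())
    return result


def evaluate(net: TGSRNet, manifest: list[tuple[str, int]], root, *,
             config: TrainConfig | None = None) -> np.ndarray:
    """Confusion matrix (rows = true stage, columns = predicted stage)."""
    config = config or TrainConfig()
    images, labels = load_images(manifest, root,
                                 input_size=config.input_size)
    cm = np.zeros((NUM_CLASSES, NUM_CLASSES), dtype=np.int64)
    for i in range(0, len(images), config.batch_size):
        x = _normalize(images[i:i + config.batch_size], config)
        pred = net.predict(x, batch_size=config.batch_size)
        for t, p in zip(labels[i:i + config.batch_size] - 1, pred):
            cm[t, p] += 1
    return cm


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Accuracy plus one-vs-rest per-class and macro statistics (percent)."""

    accuracy: float
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                "tp": self.tp.tolist(), "fp": self.fp.tolist(),
                "fn": self.fn.tolist(), "tn": self.tn.tolist(),
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
        }


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{what}: zero denominator for classes "
                      f"{np.flatnonzero(bad).tolist()}; reporting 0",
                      stacklevel=3)
    np.divide(num, den, out=out, where=~bad)
    return out


def macro_metrics(cm: np.ndarray) -> MetricsReport:
    """OvR accuracy/precision/recall/F1 from a confusion matrix, in percent.

    Each class is treated in turn as positive against all others; macro
    values are unweighted means over classes.  Zero-denominator cells yield
    0 with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    precision = _safe_ratio(tp, tp + fp, "precision") * 100.0
    recall = _safe_ratio(tp, tp + fn, "recall") * 100.0
    f1 = np.zeros_like(precision)
    nz = (precision + recall) > 0
    f1[nz] = 2 * precision[nz] * recall[nz] / (precision[nz] + recall[nz])
    return MetricsReport(
        accuracy=float(tp.sum() / total * 100.0),
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )
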