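"""Training loop, confusion-matrix metrics and one-vs-rest ROC analysis.

Training follows the reference protocol at configurable scale: rectified
Adam, batch size 64, initial learning rate 1e-4 decayed x0.1 every 20
epochs, softmax cross-entropy, best-checkpoint selection on test accuracy.
All randomness (shuffling, augmentation) flows from the config seed, so a
fixed (seed, config, dataset) triple reproduces the run exactly.

Evaluation reduces the class-by-class confusion matrix to overall accuracy
and macro one-vs-rest precision, sensitivity and specificity:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

computed per class (positives = that class, negatives = the rest) and
averaged; classes with an undefined ratio are excluded from that average
with a warning. Values are reported as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .nn import RAdam, StepLR
from .nn.functional import cross_entropy, softmax
from .nn.module import Module
from .synthetic import augment

__all__ = [
    "TrainConfig",
    "ArrayDataset",
    "train",
    "evaluate",
    "predict",
    "confusion",
    "metrics",
    "roc_ovr",
    "save_checkpoint",
    "load_checkpoint",
    "plot_confusion",
    "plot_roc",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    lr0: float = 1e-4
    lr_step_epochs: int = 20
    lr_gamma: float = 0.1
    max_epochs: int = 200
    seed: int = 0
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    augment: bool = False
    augment_kwargs: dict = field(default_factory=dict)
    device: str = "cpu"  # the stack is CPU-only; kept for config compatibility

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("batch_size must be >= 1 and max_epochs >= 0")


@dataclass
class ArrayDataset:
    """In-memory image dataset: (N, 3, H, W) float32 in [0, 1] + int labels."""

    images: np.ndarray
    labels: np.ndarray
    classes: list

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels disagree on length")

    def __len__(self):
        return len(self.labels)

    @classmethod
    def from_folder(cls, root) -> "ArrayDataset":
        """Load a folder-per-class PNG tree (any of the usual layouts:
        ``root/<class>/*.png`` or a single split directory)."""
        root = Path(root)
        class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
        if not class_dirs:
            raise FileNotFoundError(f"no class folders under {root}")
        images, labels, classes = [], [], []
        for idx, d in enumerate(class_dirs):
            classes.append(d.name)
            for f in sorted(d.glob("*.png")):
                arr = np.asarray(Image.open(f).convert("RGB"), dtype=np.float32) / 255.0
                images.append(arr.transpose(2, 0, 1))
                labels.append(idx)
        if not images:
            raise FileNotFoundError(f"no PNG files under {root}")
        return cls(np.stack(images), np.asarray(labels, dtype=np.int64), classes)


def synthetic_dataset(config, per_class: int, split: float = 0.8):
    """Generate an in-memory (train, test) pair of :class:`ArrayDataset`
    directly from the synthetic patch generator, bypassing disk. Uses the
    same per-sample seeding as :func:`crorelu.synthetic.generate_dataset`,
    so the arrays match a written dataset exactly."""
    from .synthetic import LABELS, _sample_seed, generate_patch

    train_x, train_y, test_x, test_y = [], [], [], []
    n_test = int(round((1.0 - split) * per_class))
    classes = sorted(LABELS)  # folder-order convention
    for cls_idx, label in enumerate(classes):
        label_idx = LABELS.index(label)
        for i in range(per_class):
            seed = _sample_seed(config.seed, label_idx, i)
            patch = generate_patch(label, config, np.random.default_rng(seed))
            arr = patch.image.astype(np.float32).transpose(2, 0, 1) / 255.0
            if i >= per_class - n_test:
                test_x.append(arr)
                test_y.append(cls_idx)
            else:
                train_x.append(arr)
                train_y.append(cls_idx)
    train_ds = ArrayDataset(np.stack(train_x), np.asarray(train_y, dtype=np.int64), classes)
    test_ds = (ArrayDataset(np.stack(test_x), np.asarray(test_y, dtype=np.int64), classes)
               if n_test else None)
    return train_ds, test_ds


def _head_classes(net: Module) -> int | None:
    out = None
    for _, p in net.named_parameters():
        out = p
    return None if out is None else (out.shape[0] if out.data.ndim >= 1 else None)


def _batches(n: int, batch_size: int, perm=None):
    order = perm if perm is not None else np.arange(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def predict(net: Module, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class-probability scores (N, K) in evaluation mode."""
    was_training = net.training
    net.eval()
    chunks = [softmax(net(images[idx])) for idx in _batches(len(images), batch_size)]
    net.train(was_training)
    return np.concatenate(chunks)


def evaluate(net: Module, data: ArrayDataset, batch_size: int = 64):
    """Returns (labels, predictions, scores) on a dataset."""
    scores = predict(net, data.images, batch_size)
    return data.labels, scores.argmax(axis=1), scores


def train(net: Module, train_data: ArrayDataset, config: TrainConfig,
          test_data: ArrayDataset | None = None):
    """Train in place; returns (history DataFrame, best state dict).

    History columns: epoch (1-based), lr, train_loss, train_acc, test_acc.
    The best state is selected on test accuracy (train accuracy when no
    test set is given), mirroring test-set-feedback checkpointing.
    """
    if len(train_data) == 0:
        raise ValueError("empty training dataset")
    n_classes = len(train_data.classes)
    head = _head_classes(net)
    if head is not None and head != n_classes:
        raise ValueError(f"network head emits {head} classes but dataset has {n_classes}")
    if train_data.labels.max() >= n_classes or train_data.labels.min() < 0:
        raise ValueError("labels out of range for the declared class list")

    rng = np.random.default_rng(config.seed)
    optimizer = RAdam(net.parameters(), lr=config.lr0, betas=config.betas,
                      eps=config.eps, weight_decay=config.weight_decay)
    scheduler = StepLR(optimizer, step_size=config.lr_step_epochs, gamma=config.lr_gamma)
    history = []
    best_acc, best_state = -np.inf, net.state_dict()
    for epoch in range(config.max_epochs):
        scheduler.set_epoch(epoch)
        net.train()
        perm = rng.permutation(len(train_data))
        losses, correct = [], 0
        for idx in _batches(len(train_data), config.batch_size, perm):
            x = train_data.images[idx]
            if config.augment:
                x = np.stack([
                    augment(im.transpose(1, 2, 0), rng, **config.augment_kwargs).transpose(2, 0, 1)
                    for im in x
                ]).astype(np.float32)
            y = train_data.labels[idx]
            logits = net(x)
            loss, grad = cross_entropy(logits, y)
            net.zero_grad()
            net.backward(grad.astype(logits.dtype))
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y).sum())
        train_loss = float(np.sum(losses) / len(train_data))
        train_acc = correct / len(train_data)
        if test_data is not None:
            labels, preds, _ = evaluate(net, test_data, config.batch_size)
            test_acc = float((labels == preds).mean())
        else:
            test_acc = np.nan
        history.append({"epoch": epoch + 1, "lr": scheduler.lr_at(epoch),
                        "train_loss": train_loss, "train_acc": train_acc,
                        "test_acc": test_acc})
        select = test_acc if test_data is not None else train_acc
        if select > best_acc:
            best_acc, best_state = select, net.state_dict()
    return pd.DataFrame(history, columns=["epoch", "lr", "train_loss", "train_acc", "test_acc"]), best_state


# ---------------------------------------------------------------------------
# metrics


def confusion(labels, predictions, n_classes: int) -> np.ndarray:
    """Counts[t, p] = #{i : labels_i = t, predictions_i = p}."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for name, a in (("labels", labels), ("predictions", predictions)):
        if a.size and (a.min() < 0 or a.max() >= n_classes):
            raise ValueError(f"{name} contain class indices outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, predictions), 1)
    return cm


def metrics(cm: np.ndarray) -> dict:
    """Overall accuracy plus macro one-vs-rest precision, sensitivity and
    specificity, as percentages. Per-class values are returned under
    ``per_class`` (NaN where the ratio is undefined)."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    tp = np.diag(cm).astype(np.float64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    per = {}
    for name, num, den in (("precision", tp, tp + fp),
                           ("sensitivity", tp, tp + fn),
                           ("specificity", tn, tn + fp)):
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / den, np.nan)
        undefined = np.nonzero(den == 0)[0]
        if undefined.size:
            warnings.warn(f"{name} undefined for class(es) {undefined.tolist()}; "
                          "excluded from the macro average", stacklevel=2)
        per[name] = vals * 100.0
    out = {"accuracy": float(tp.sum() / total * 100.0)}
    for name in ("precision", "sensitivity", "specificity"):
        vals = per[name]
        out[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    out["per_class"] = per
    out["n_classes"] = int(k)
    return out


def roc_ovr(scores: np.ndarray, labels: np.ndarray) -> dict:
    """One-vs-rest ROC curves by threshold sweep over the unique scores of
    each class column, with trapezoidal AUC. Returns {class_index: {fpr,
    tpr, thresholds, auc}}; AUC is NaN for classes absent from ``labels``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 2 or len(scores) != len(labels):
        raise ValueError("scores must be (n, K) aligned with labels")
    curves = {}
    for k in range(scores.shape[1]):
        s = scores[:, k]
        y = labels == k
        pos, neg = int(y.sum()), int((~y).sum())
        order = np.argsort(-s, kind="stable")
        s_sorted, y_sorted = s[order], y[order]
        # last index of each distinct score value = one sweep threshold
        distinct = np.nonzero(np.diff(s_sorted))[0]
        idx = np.r_[distinct, len(s_sorted) - 1]
        tps = np.cumsum(y_sorted)[idx]
        fps = np.cumsum(~y_sorted)[idx]
        if pos == 0 or neg == 0:
            warnings.warn(f"class {k} has no {'positive' if pos == 0 else 'negative'} "
                          "examples; AUC undefined", stacklevel=2)
            auc = float("nan")
            tpr = tps / max(pos, 1)
            fpr = fps / max(neg, 1)
        else:
            tpr = tps / pos
            fpr = fps / neg
            auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
        curves[k] = {"fpr": np.r_[0.0, fpr], "tpr": np.r_[0.0, tpr],
                     "thresholds": np.r_[np.inf, s_sorted[idx]], "auc": auc}
    return curves


# ---------------------------------------------------------------------------
# persistence & plots


def save_checkpoint(net: Module, path):
    np.savez(path, **net.state_dict())


def load_checkpoint(net: Module, path):
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})


def plot_confusion(cm: np.ndarray, classes, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    ax.set_xticks(range(len(classes)), classes, rotation=45, ha="right")
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: dict, classes, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for k, c in curves.items():
        name = classes[k] if k < len(classes) else str(k)
        ax.plot(c["fpr"], c["tpr"], label=f"{name} (AUC={c['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
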