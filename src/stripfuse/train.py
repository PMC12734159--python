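"""Training loop, checkpointing, and model evaluation.

Defaults follow the tuned recipe the model was designed around: AdamW with
learning rate 1e-4 and decoupled weight decay 1e-4, batch size 32, dropout
0.3, cross-entropy loss, 50 epochs.  After each epoch the internal
validation accuracy is measured and the parameters are snapshotted whenever
it improves, so the returned checkpoint is always the best-validation
model.  The per-epoch history (train/val loss and accuracy) is recorded and
can be written as a delimited text file.

All randomness (shuffling, augmentation, dropout) flows from the config
seed, so two runs with the same seed produce bit-identical histories on the
same machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor, softmax_cross_entropy
from .data import DatasetManifest
from .metrics import MetricsReport, compute_report
from .model import ModelConfig, StripFusionNet, build_model
from .optim import SGD, AdamW, RMSprop
from .preprocess import AugmentConfig, augment, load_image, preprocess_chain
from .synth import CLASS_LABELS

__all__ = [
    "TrainConfig",
    "TrainResult",
    "DivergenceError",
    "load_split_arrays",
    "train_model",
    "evaluate_model",
    "save_checkpoint",
    "load_checkpoint",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and input-pipeline settings."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adamw"
    weight_decay: float = 1e-4
    epochs: int = 50
    dropout: float = 0.3
    loss: str = "cross_entropy"
    seed: int = 0
    image_side: int = 224
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    unsharp_radius: float = 100.0
    unsharp_amount: float = 1.0
    sobel_weight: float = 0.5

    def __post_init__(self):
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_accuracy: float

    def write_history(self, path) -> None:
        self.history.to_csv(path, sep="\t", index=False)


def _make_optimizer(net: StripFusionNet, cfg: TrainConfig):
    params = list(net.parameters())
    name = cfg.optimizer.lower()
    if name == "adamw":
        return AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    if name == "adam":
        return AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                     decoupled=False)
    if name == "rmsprop":
        return RMSprop(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    if name == "sgd":
        return SGD(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def load_split_arrays(
    manifest: DatasetManifest,
    split: str,
    cfg: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Load and preprocess one split into (N, 1, side, side) and labels."""
    subset = manifest.subset(split)
    if len(subset) == 0:
        raise ValueError(f"split {split!r} is empty")
    images, labels = [], []
    for record in subset:
        img = load_image(record.path)
        img = preprocess_chain(
            img,
            side=cfg.image_side,
            unsharp_radius=cfg.unsharp_radius,
            unsharp_amount=cfg.unsharp_amount,
            sobel_weight=cfg.sobel_weight,
        )
        images.append(img.astype(np.float32))
        labels.append(CLASS_LABELS.index(record.class_label))
    x = np.stack(images)[:, None, :, :]
    return x, np.asarray(labels, dtype=int)


def _forward_accuracy(net, x, y, batch_size=64):
    """Eval-mode loss and accuracy over a whole array, batched."""
    net.eval()
    losses, correct = [], 0
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = net.forward_logits(Tensor(xb))
        loss = softmax_cross_entropy(logits, yb)
        losses.append(float(loss.data) * len(xb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def assert_no_leakage(manifest: DatasetManifest) -> None:
    """Check that no global ID appears in more than one split."""
    seen: dict[str, str] = {}
    for record in manifest:
        if record.global_id in seen and seen[record.global_id] != record.split:
            raise ValueError(f"global ID {record.global_id} leaks across splits")
        seen[record.global_id] = record.split


def train_model(
    net: StripFusionNet,
    manifest: DatasetManifest,
    cfg: TrainConfig,
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Minimise cross-entropy on the train split; checkpoint on best val accuracy.

    ``arrays`` may carry preloaded ``{"train": (x, y), "internal_val": (x, y)}``
    tensors to skip re-reading images (the pipeline uses this when training
    several variants on one dataset).
    """
    assert_no_leakage(manifest)
    if arrays is None:
        arrays = {
            "train": load_split_arrays(manifest, "train", cfg),
            "internal_val": load_split_arrays(manifest, "internal_val", cfg),
        }
    x_train, y_train = arrays["train"]
    x_val, y_val = arrays["internal_val"]

    rng = np.random.default_rng(cfg.seed)
    optimizer = _make_optimizer(net, cfg)
    rows = []
    best_state: dict[str, np.ndarray] | None = None
    best_epoch, best_val_acc = 0, -np.inf
    for epoch in range(1, cfg.epochs + 1):
        tic = time.perf_counter()
        net.train()
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = x_train[idx]
            if cfg.augment:
                xb = np.stack(
                    [augment(im[0], rng, cfg.augment_config) for im in xb]
                ).astype(np.float32)[:, None]
            yb = y_train[idx]
            logits = net.forward_logits(Tensor(xb))
            loss = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"training loss became {loss.data} at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int((logits.data.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _forward_accuracy(net, x_val, y_val)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(x_train),
                "train_acc": epoch_correct / len(x_train),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_epoch = epoch
            best_state = net.state_dict()
        if verbose:
            print(
                f"[{time.strftime('%H:%M:%S')}] epoch {epoch:3d} "
                f"train_loss {rows[-1]['train_loss']:.4f} "
                f"train_acc {rows[-1]['train_acc']:.3f} "
                f"val_loss {val_loss:.4f} val_acc {val_acc:.3f} "
                f"({time.perf_counter() - tic:.1f}s)"
            )
    history = pd.DataFrame(rows)
    return TrainResult(history, best_state, best_epoch, float(best_val_acc))


def evaluate_model(
    net: StripFusionNet,
    manifest: DatasetManifest,
    cfg: TrainConfig,
    split: str = "test",
    arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> MetricsReport:
    """Deterministic eval-mode metrics report on one split."""
    x, y = arrays if arrays is not None else load_split_arrays(manifest, split, cfg)
    net.eval()
    scores = []
    for lo in range(0, len(x), 64):
        scores.append(net.predict_proba(x[lo : lo + 64]))
    scores = np.concatenate(scores)
    y_pred = scores.argmax(axis=1)
    return compute_report(y, y_pred, list(CLASS_LABELS), scores=scores)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, net: StripFusionNet, state: dict | None = None,
                    meta: dict | None = None) -> None:
    """Write named parameter/buffer arrays plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:  # write to the exact path, whatever its suffix
        np.savez(fh, **(state if state is not None else net.state_dict()))
    sidecar = {"model_config": asdict(net.cfg), "meta": meta or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_checkpoint(path) -> StripFusionNet:
    """Rebuild the network recorded at ``path`` (expects the JSON sidecar)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    raw = sidecar["model_config"]
    for key in ("spatial_widths", "residual_widths", "residual_strides"):
        raw[key] = tuple(raw[key])
    net = build_model(ModelConfig(**raw))
    with np.load(path) as archive:
        net.load_state_dict({k: archive[k] for k in archive.files})
    return net
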