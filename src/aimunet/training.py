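"""Training loop: Adam, binary cross-entropy, tracked Dice/IoU/recall/precision.

Default protocol: batch size 3, 100 epochs, learning rate 1e-3, a 0.20
validation division of the training pairs, optional early stopping on
validation loss with patience 5.  Per-epoch metrics are computed on the
held-out fraction with predictions thresholded at 0.5; the weights with the
best validation loss are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._rand import keyed_rng
from .config import TrainConfig
from .evaluate import ConfusionCounts, precision as _precision, recall as _recall
from .network.runtime import Network

EPS = 1e-7  # prediction clipping before the logarithm


def bce_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over pixels of -[g log p + (1-g) log(1-p)], with p clipped to
    [EPS, 1-EPS]."""
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))


def bce_grad(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d pred, matching the clipping of :func:`bce_loss`."""
    p = np.clip(np.asarray(pred, dtype=np.float64), EPS, 1.0 - EPS)
    g = np.asarray(truth, dtype=np.float64)
    return ((p - g) / (p * (1.0 - p)) / p.size).astype(np.float32)


@dataclass
class TrainHistory:
    """Per-epoch series; all metric values lie in [0, 1] and losses are >= 0."""

    loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    dice: List[float] = field(default_factory=list)
    iou: List[float] = field(default_factory=list)
    recall: List[float] = field(default_factory=list)
    precision: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def as_dict(self) -> Dict[str, List[float]]:
        return {k: list(v) for k, v in self.__dict__.items()}


class Adam:
    """Adaptive moment estimation with the conventional (0.9, 0.999) moments."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value[...] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _soft_metrics(probs: np.ndarray, truth: np.ndarray,
                  threshold: float = 0.5) -> Dict[str, float]:
    pred = probs > threshold
    g = truth > 0.5
    tp = int(np.sum(pred & g))
    fp = int(np.sum(pred & ~g))
    fn = int(np.sum(~pred & g))
    denom = 2 * tp + fp + fn
    dice = 2 * tp / denom if denom else 1.0
    union = tp + fp + fn
    iou = tp / union if union else 1.0
    c = ConfusionCounts(tp=tp, fp=fp, tn=int(np.sum(~pred & ~g)), fn=fn)
    return {"dice": dice, "iou": iou, "recall": _recall(c), "precision": _precision(c)}


def _as_batch(images: Sequence, masks: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    xs, gs = [], []
    for im in images:
        px = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        if hasattr(im, "intensity_state") and im.intensity_state != "normalized":
            raise ValueError("training inputs must be normalized slices")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("training inputs must lie in [0, 1] (normalize first)")
        xs.append(px[..., None])
    for mk in masks:
        px = mk.pixels if hasattr(mk, "pixels") else np.asarray(mk)
        gs.append(px[..., None])
    return (np.stack(xs).astype(np.float32), np.stack(gs).astype(np.float32))


def train(net: Network, images: Sequence, masks: Sequence,
          config: Optional[TrainConfig] = None,
          max_steps: Optional[int] = None) -> TrainHistory:
    """Run the training protocol on (image, mask) pairs, in place on ``net``.

    ``images`` are normalized slices (CTSlice or arrays in [0, 1]) matching
    the network input size; ``masks`` the paired binary masks.  Validation
    metrics use a held-out ``val_fraction`` of the pairs; if that rounds to
    zero pairs, metrics are computed on the training pairs themselves.
    The best-validation-loss weights are restored at the end.  ``max_steps``
    optionally caps the number of optimizer updates (for reduced
    experiments).
    """
    config = config or TrainConfig()
    config.validate()
    if len(images) == 0:
        raise ValueError("training dataset is empty")
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up one-to-one")
    x, g = _as_batch(images, masks)
    history = TrainHistory()
    if config.epochs == 0:
        return history

    rng = keyed_rng(config.seed, "train")
    n = len(x)
    n_val = round(config.val_fraction * n)
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training pairs")
    if len(val_idx) == 0:
        val_idx = train_idx

    opt = Adam(net.params(), lr=config.learning_rate)
    best_val, best_weights, bad_epochs = np.inf, None, 0
    steps = 0
    for epoch in range(config.epochs):
        order = keyed_rng(config.seed, "epoch", epoch).permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            if max_steps is not None and steps >= max_steps:
                break
            idx = order[start:start + config.batch_size]
            probs = net.forward(x[idx], training=True)
            epoch_losses.append(bce_loss(probs, g[idx]))
            net.zero_grad()
            net.backward(bce_grad(probs, g[idx]))
            opt.step()
            steps += 1

        val_probs = net.predict(x[val_idx], batch_size=config.batch_size)
        val_loss = bce_loss(val_probs, g[val_idx])
        metrics = _soft_metrics(val_probs, g[val_idx])
        history.loss.append(float(np.mean(epoch_losses)) if epoch_losses else val_loss)
        history.val_loss.append(val_loss)
        for name in ("dice", "iou", "recall", "precision"):
            getattr(history, name).append(metrics[name])

        if val_loss < best_val:
            best_val, best_weights, bad_epochs = val_loss, net.get_weights(), 0
        else:
            bad_epochs += 1
            if config.early_stopping and bad_epochs >= config.patience:
                break
        if max_steps is not None and steps >= max_steps:
            break

    if best_weights is not None:
        net.set_weights(best_weights)
    return history
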