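"""Training loop (cross-entropy + Adam) and model-size reporting.

The protocol is deliberately plain: softmax cross-entropy over the two
classes at every query point, Adam at a constant learning rate, no
augmentation (a hook exists, default off), best-checkpoint selection by
validation Dice.  Every source of randomness — weight init, shuffling —
flows from the config seed, so identical configs reproduce identical
histories bit for bit on CPU.
"""

from __future__ import annotations

import copy
import dataclasses
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import fa_decoder as fa
from . import metrics as mx
from .model import FANet
from .nn import Adam, Tensor, flop_meter
from .nn import autodiff as ad


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    input_side: int = 256
    include_lesion_free_slices: bool = True
    max_steps: int | None = None
    points_per_image: int | None = None  # None = decode the full grid
    class_weights: tuple[float, float] | None = None
    augment: Callable | None = None  # hook; default off

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")

    @staticmethod
    def from_yaml(path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(TrainConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown training config keys: {sorted(unknown)}")
        if "class_weights" in raw and raw["class_weights"] is not None:
            raw["class_weights"] = tuple(raw["class_weights"])
        return TrainConfig(**raw)


def cross_entropy_loss(logits: Tensor, labels: np.ndarray,
                       class_weights=None) -> Tensor:
    """Mean per-pixel negative log-probability of the true class."""
    w = None if class_weights is None else np.asarray(class_weights, float)
    return ad.softmax_cross_entropy(logits, np.asarray(labels, dtype=np.int64), w)


def _labels_at(points: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Ground-truth class at each query point (nearest mask pixel)."""
    h, w = mask.shape
    r, c = fa.nearest_indices(points, h, w)
    return mask[r, c].astype(np.int64)


@dataclasses.dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_val_dice: float


def _val_dice(model: FANet, images: np.ndarray, masks: np.ndarray) -> float:
    preds = [model.predict(img).pixels for img in images]
    return mx.evaluate(preds, list(masks), mode="pooled")["Dice"]


def train(model: FANet, train_images: np.ndarray, train_masks: np.ndarray,
          cfg: TrainConfig, val_images: np.ndarray | None = None,
          val_masks: np.ndarray | None = None) -> TrainResult:
    """Optimise ``model`` in place; returns the history and best weights.

    ``train_images`` is (N, S, S) windowed to [0, 1]; ``train_masks`` is
    (N, S, S) binary.  Validation (optional) is scored by pooled Dice after
    every epoch and the best-scoring state is retained.
    """
    n = len(train_images)
    if n == 0:
        raise ValueError("empty training set")
    if len(train_masks) != n:
        raise ValueError("images and masks are misaligned")
    side = train_images.shape[1]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    full_grid = fa.QueryGrid.full_grid((side, side)).points
    weights = None if cfg.class_weights is None else np.asarray(cfg.class_weights)

    history: list[dict] = []
    best_state = model.state_dict()
    best_dice = -1.0
    step = 0
    stop = False
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = train_images[idx][:, None].astype(np.float32)
            mb = train_masks[idx]
            if cfg.augment is not None:
                xb, mb = cfg.augment(xb, mb, rng)
            if cfg.points_per_image is None:
                points = full_grid
            else:
                sel = rng.choice(full_grid.shape[0], size=cfg.points_per_image,
                                 replace=False)
                points = full_grid[sel]
            labels = np.concatenate([_labels_at(points, m) for m in mb])
            logits = model(Tensor(xb), points)
            loss = cross_entropy_loss(logits, labels, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                stop = True
                break
        row = {"epoch": epoch, "step": step,
               "train_loss": float(np.mean(losses))}
        if val_images is not None and len(val_images):
            model.eval()
            vd = _val_dice(model, val_images, val_masks)
            row["val_dice"] = vd
            if vd > best_dice:
                best_dice = vd
                best_state = model.state_dict()
        else:
            best_state = model.state_dict()
        history.append(row)
        if stop:
            break
    model.eval()
    return TrainResult(history=pd.DataFrame(history), best_state=best_state,
                       best_val_dice=best_dice)


# ---------------------------------------------------------------------------
# Model-size reporting

def count_parameters(model) -> int:
    """Exact trainable-parameter count."""
    return int(sum(p.data.size for p in model.parameters()))


def estimate_flops(model: FANet, input_shape: tuple[int, int, int, int],
                   n_points: int | None = None) -> int:
    """FLOP estimate for one forward pass at ``input_shape`` (N,1,S,S).

    Counting rule: 2 x multiply-accumulates of convolutions and linear
    layers (normalisation, activations, gathers and the position encoding
    are excluded).  ``n_points`` is the number of decoded query points
    (defaults to the full S x S grid).
    """
    n, c, s, _ = input_shape
    if n_points is None:
        n_points = s * s
    pts = fa.QueryGrid.full_grid((1, n_points)).points
    x = Tensor(np.zeros(input_shape, dtype=np.float32))
    was_training = model.training
    model.eval()
    try:
        with flop_meter() as meter, ad.no_grad():
            model(x, pts)
    finally:
        model.train(was_training)
    return int(2 * sum(m["macs"] for m in meter))
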