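"""Training loop and sliding-window inference.

Training is patch-based: every step draws a patch centered (with jitter) on
a random foreground voxel, so the loss always sees the vessel.  Online
augmentation applies the random 3D affine (rotation 0-15 deg, scale
0.7-1.3, translation) to the whole image/mask pair before patch extraction.
Optimisation is Adam on the soft-DICE loss; everything is reproducible from
(data seed, model seed).

Inference tiles the volume with overlapping patches and averages the
per-class probabilities, then takes the per-voxel argmax (classes are
mutually exclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..augment import TrainingCase, random_affine_3d
from ..core import LabelMask, Volume
from .losses import soft_dice_loss_grad
from .unet import AttentionUNet3D

log = logging.getLogger(__name__)


@dataclass
class TrainHistory:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    def mean_loss(self, epochs: slice) -> float:
        df = self.to_frame()
        return float(df["train_loss"].iloc[epochs].mean())


def _pad_to(arr: np.ndarray, shape: tuple[int, ...], cval=0) -> np.ndarray:
    pads = []
    for s, t in zip(arr.shape, shape):
        extra = max(t - s, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="constant", constant_values=cval)
    return arr


def _sample_patch(img: np.ndarray, lab: np.ndarray, patch: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    img = _pad_to(img, (patch,) * 3)
    lab = _pad_to(lab, (patch,) * 3)
    fg = np.argwhere(lab != 0)
    if len(fg):
        c = fg[rng.integers(0, len(fg))]
        c = c + rng.integers(-patch // 4, patch // 4 + 1, size=3)
    else:
        c = np.array([s // 2 for s in lab.shape])
    lo = np.clip(c - patch // 2, 0, np.array(lab.shape) - patch)
    sl = tuple(slice(int(a), int(a) + patch) for a in lo)
    return img[sl], lab[sl]


def train(model: AttentionUNet3D, cases: list[TrainingCase],
          val_cases: list[TrainingCase] | None = None, *,
          epochs: int | None = None, online_augment: bool = True,
          patches_per_case: int = 2, val_every: int = 5,
          early_stop_loss: float | None = 0.02,
          checkpoint_dir: str | Path | None = None,
          seed: int | None = None) -> TrainHistory:
    """Fit ``model`` on ``cases``; returns the per-epoch history.

    Raises a data error when no case contains any foreground voxel.
    """
    if len(cases) < 2:
        raise ValueError("training needs >= 2 cases")
    if not any((c.mask.data != 0).any() for c in cases):
        raise ValueError("no foreground voxels in any training case")
    cfg = model.cfg
    n_epochs = epochs if epochs is not None else cfg.epochs
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    opt = model.make_optimizer()
    history = TrainHistory()
    best_val = -1.0
    for epoch in range(n_epochs):
        order = rng.permutation(len(cases))
        losses = []
        pending = 0
        opt.zero_grad()
        for ci in order:
            case = cases[ci]
            img, msk = case.image, case.mask
            if online_augment:
                img, msk, _ = random_affine_3d(img, msk,
                                               int(rng.integers(0, 2**31 - 1)))
            for _ in range(patches_per_case):
                xi, ti = _sample_patch(np.asarray(img.data, np.float32),
                                       msk.data, cfg.patch_size, rng)
                probs = model.forward(xi[None])
                loss, grad = soft_dice_loss_grad(probs, ti)
                model.backward(grad)
                losses.append(loss)
                pending += 1
                if pending >= cfg.batch_size:
                    opt.step()
                    opt.zero_grad()
                    pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        run_val = val_cases and (epoch % val_every == val_every - 1
                                 or epoch == n_epochs - 1)
        if run_val:
            row["val_dice_fg"] = float(np.mean(
                [validation_dice(model, c) for c in val_cases]))
            if checkpoint_dir and row["val_dice_fg"] > best_val:
                best_val = row["val_dice_fg"]
                model.save(Path(checkpoint_dir) / "best.npz")
        history.rows.append(row)
        log.info("epoch %d: %s", epoch, row)
        if early_stop_loss is not None and row["train_loss"] < early_stop_loss:
            break
    if checkpoint_dir:
        model.save(Path(checkpoint_dir) / "last.npz")
        history.to_csv(Path(checkpoint_dir) / "history.csv")
    return history


def validation_dice(model: AttentionUNet3D, case: TrainingCase) -> float:
    """Combined-foreground DICE of the model's prediction on one case."""
    probs = predict(model, case.image)
    pred_fg = probs[0] < 0.5  # background probability below half = foreground
    true_fg = case.mask.data != 0
    inter = np.count_nonzero(pred_fg & true_fg)
    denom = np.count_nonzero(pred_fg) + np.count_nonzero(true_fg)
    return 1.0 if denom == 0 else 2.0 * inter / denom


def predict(model: AttentionUNet3D, v: Volume, patch_size: int | None = None,
            overlap: float = 0.5) -> np.ndarray:
    """Sliding-window inference; returns per-class probabilities
    ``(out_classes, *v.shape)`` in the input geometry."""
    patch = patch_size or model.cfg.patch_size
    data = np.asarray(v.data, np.float32)
    orig_shape = data.shape
    target = tuple(max(s, patch) for s in orig_shape)
    if target != orig_shape:
        log.info("padding %s -> %s for patch size %d", orig_shape, target, patch)
    data = _pad_to(data, target)
    stride = max(int(patch * (1.0 - overlap)), 1)
    starts = [_window_starts(s, patch, stride) for s in data.shape]
    acc = np.zeros((model.cfg.out_classes,) + data.shape, np.float32)
    cnt = np.zeros(data.shape, np.float32)
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + patch), slice(sy, sy + patch),
                      slice(sz, sz + patch))
                probs = model.forward(data[sl][None])
                acc[(slice(None),) + sl] += probs
                cnt[sl] += 1
    acc /= cnt
    # undo padding
    off = [(t - s) // 2 for s, t in zip(orig_shape, target)]
    sl = tuple(slice(o, o + s) for o, s in zip(off, orig_shape))
    return acc[(slice(None),) + sl]


def _window_starts(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, stride))
    starts.append(size - patch)
    return starts


def probs_to_mask(probs: np.ndarray, like: Volume) -> LabelMask:
    """Per-voxel argmax of a probability stack, in the geometry of ``like``."""
    return LabelMask(np.argmax(probs, axis=0).astype(np.uint8),
                     like.spacing, like.origin)
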