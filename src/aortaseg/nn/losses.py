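"""Soft multi-class DICE loss.

The DICE coefficient between binary sets A and B is ``2|A n B| / (|A|+|B|)``.
Its soft relaxation replaces set membership with predicted probabilities:
for class c, ``dice_c = (2 sum(p_c g_c) + eps) / (sum p_c + sum g_c + eps)``
and the loss is ``1 - mean_c dice_c`` over the non-background classes.  With
``eps`` the loss of an empty class against an empty prediction is 0 (two
empty sets are in perfect agreement by convention).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(X, Y, Z) int labels -> (n_classes, X, Y, Z) float32 one-hot."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def soft_dice_loss(probs: np.ndarray, target: np.ndarray, eps: float = EPS,
                   include_background: bool = False) -> float:
    """Scalar loss; ``probs`` (C, ...) on the simplex, ``target`` (C, ...)
    one-hot or (...) integer labels."""
    loss, _ = soft_dice_loss_grad(probs, target, eps, include_background,
                                  need_grad=False)
    return loss


def soft_dice_loss_grad(probs: np.ndarray, target: np.ndarray, eps: float = EPS,
                        include_background: bool = False, need_grad: bool = True
                        ) -> tuple[float, np.ndarray | None]:
    """Loss and its gradient with respect to ``probs``."""
    c = probs.shape[0]
    if target.ndim == probs.ndim - 1:
        target = one_hot(np.asarray(target), c)
    if target.shape != probs.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {target.shape}")
    classes = range(0 if include_background else 1, c)
    n_cls = len(list(classes))
    if n_cls == 0:
        raise ValueError("no classes to evaluate")
    loss = 0.0
    grad = np.zeros_like(probs) if need_grad else None
    for cl in range(0 if include_background else 1, c):
        p = probs[cl].ravel().astype(np.float64)
        g = target[cl].ravel().astype(np.float64)
        inter = float(p @ g)
        denom = float(p.sum() + g.sum()) + eps
        dice = (2.0 * inter + eps) / denom
        loss += (1.0 - dice) / n_cls
        if need_grad:
            # d(1-dice)/dp = -(2 g denom - (2 inter + eps)) / denom^2
            gp = -(2.0 * g * denom - (2.0 * inter + eps)) / denom**2
            grad[cl] = (gp / n_cls).reshape(probs.shape[1:]).astype(np.float32)
    return float(loss), grad
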