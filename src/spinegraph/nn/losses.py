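"""Segmentation losses.

Training uses a fused softmax + (Dice + cross-entropy) op on logits with a
hand-derived gradient; a plain NumPy evaluation path over probability maps
is exposed for analysis.  The soft Dice per class uses an additive smooth
term in numerator and denominator, so a class absent from both prediction
and target scores a perfect 1 and contributes no gradient pressure.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, _result

__all__ = ["one_hot", "soft_dice_ce", "dice_ce_value"]

SMOOTH = 1e-5
TINY = 1e-12


def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(1, C, *S) float32 one-hot encoding of an integer label grid."""
    t = np.asarray(target)
    if t.min() < 0 or t.max() >= n_classes:
        raise ValueError(
            f"target labels outside 0..{n_classes - 1}: range "
            f"[{t.min()}, {t.max()}]")
    oh = np.zeros((n_classes,) + t.shape, dtype=np.float32)
    np.put_along_axis(oh, t[None].astype(np.int64), 1.0, axis=0)
    return oh[None]


def _dice_ce_terms(p: np.ndarray, y: np.ndarray):
    """Return (ce, dice_loss, per-class sums) for probs/one-hot (1, C, *S)."""
    axes = (0,) + tuple(range(2, p.ndim))
    nvox = int(np.prod([p.shape[a] for a in axes]))
    ce = float(-np.sum(y * np.log(p + TINY), dtype=np.float64) / nvox)
    inter = (p * y).sum(axis=axes, dtype=np.float64)
    psum = p.sum(axis=axes, dtype=np.float64)
    ysum = y.sum(axis=axes, dtype=np.float64)
    dice = (2.0 * inter + SMOOTH) / (psum + ysum + SMOOTH)
    return ce, float(1.0 - dice.mean()), (inter, psum, ysum, nvox)


def dice_ce_value(probs: np.ndarray, target: np.ndarray, dice_w: float = 1.0,
                  ce_w: float = 1.0) -> float:
    """Evaluate Dice+CE on a probability map (no gradients)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == np.asarray(target).ndim + 1:
        probs = probs[None]
    y = one_hot(target, probs.shape[1]).astype(np.float64)
    ce, dice_loss, _ = _dice_ce_terms(probs, y)
    return ce_w * ce + dice_w * dice_loss


def soft_dice_ce(logits: Tensor, target: np.ndarray, dice_w: float = 1.0,
                 ce_w: float = 1.0) -> Tensor:
    """Differentiable Dice + cross-entropy on logits (1, C, *S).

    ``target`` is either an integer label grid or an already-encoded
    per-voxel class distribution (1, C, *S) with unit voxel sums (used for
    block-averaged deep-supervision targets).
    """
    z = logits.data
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    p = e / e.sum(axis=1, keepdims=True)
    target = np.asarray(target)
    if np.issubdtype(target.dtype, np.floating) and target.ndim == z.ndim:
        y = target.astype(np.float32, copy=False)
        if y.shape != z.shape:
            raise ValueError(f"soft target shape {y.shape} != logits {z.shape}")
    else:
        y = one_hot(target, z.shape[1])
    ce, dice_loss, (inter, psum, ysum, nvox) = _dice_ce_terms(p, y)
    loss = ce_w * ce + dice_w * dice_loss
    denom = psum + ysum + SMOOTH
    n_classes = z.shape[1]
    cdim = (1, -1) + (1,) * (z.ndim - 2)

    def backward(g):
        # Dice part goes through the softmax Jacobian; the CE part uses the
        # closed-form fused gradient (p - y)/V.
        ddice = -(2.0 * y * denom.reshape(cdim)
                  - (2.0 * inter + SMOOTH).reshape(cdim)) / (denom ** 2).reshape(cdim)
        gp = (dice_w * ddice / n_classes).astype(p.dtype)
        dot = (gp * p).sum(axis=1, keepdims=True)
        grad = p * (gp - dot) + (ce_w / nvox) * (p - y)
        logits.accumulate((g * grad).astype(logits.data.dtype, copy=False))

    return _result(np.float64(loss), (logits,), backward)
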