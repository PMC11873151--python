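"""Losses and probability utilities shared by both training stages."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["log_softmax", "softmax", "cross_entropy", "kl_divergence",
           "soft_dice_loss", "one_hot"]


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(logits.data.max(axis=axis, keepdims=True))  # shift, no grad
    z = logits - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(logits, axis=axis).exp()


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[np.asarray(labels, dtype=int)]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy; integer labels, logits (N, C)."""
    logp = log_softmax(logits, axis=-1)
    oh = one_hot(labels, logits.shape[-1])
    return -(logp * oh).sum(axis=-1).mean()


def kl_divergence(p: Tensor, log_q: Tensor, axis: int = -1) -> Tensor:
    """KL(p || q) with q given in log space; mean over leading axes."""
    log_p = (p + 1e-12).log()
    return (p * (log_p - log_q)).sum(axis=axis).mean()


def soft_dice_loss(logits: Tensor, masks: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 − soft Dice of sigmoid(logits) vs binary masks, (N, 1, H, W)."""
    p = logits.sigmoid()
    m = Tensor(np.asarray(masks, dtype=np.float64))
    inter = (p * m).sum(axis=(1, 2, 3))
    denom = p.sum(axis=(1, 2, 3)) + m.sum(axis=(1, 2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice.mean()
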