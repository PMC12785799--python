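"""Multiclass focal loss.

Per sample: ``L = -alpha * (1 - p_t)**gamma * log(p_t)`` where ``p_t`` is the
predicted probability of the true class; the batch mean is returned.  With
``gamma = 0`` and ``alpha = 1`` this is categorical cross-entropy.  ``alpha``
is applied as a scalar on every class; a per-class vector is accepted for
explicit minority weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import softmax

_P_CLIP = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    alpha: float | np.ndarray = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _alpha_t(params: FocalLossParams, one_hot: np.ndarray) -> np.ndarray:
    a = np.asarray(params.alpha)
    if a.ndim == 0:
        return np.full(one_hot.shape[0], float(a))
    return one_hot @ a


def focal_loss(
    probabilities: np.ndarray,
    one_hot_targets: np.ndarray,
    params: FocalLossParams = FocalLossParams(),
) -> float:
    """Mean focal loss over a batch of probability rows."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(one_hot_targets, dtype=float)
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    pt = np.clip((p * y).sum(axis=-1), _P_CLIP, 1.0)
    at = _alpha_t(params, y)
    return float(np.mean(-at * (1.0 - pt) ** params.gamma * np.log(pt)))


def focal_loss_with_grad(
    logits: np.ndarray,
    one_hot_targets: np.ndarray,
    params: FocalLossParams = FocalLossParams(),
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the logits (softmax inside).

    Using dp_t/dz_j = p_t (y_j - p_j):
    dL/dz_j = dL/dp_t * p_t * (y_j - p_j), averaged over the batch.
    """
    y = np.asarray(one_hot_targets, dtype=float)
    p = softmax(np.asarray(logits, dtype=np.float64))
    pt = np.clip((p * y).sum(axis=-1), _P_CLIP, 1.0 - 1e-12)
    at = _alpha_t(params, y)
    g = params.gamma
    loss = float(np.mean(-at * (1.0 - pt) ** g * np.log(pt)))
    # dL/dpt
    dl_dpt = at * (g * (1.0 - pt) ** (g - 1.0) * np.log(pt) - (1.0 - pt) ** g / pt)
    dlogits = (dl_dpt * pt)[:, None] * (y - p) / len(y)
    return loss, dlogits.astype(np.float32)
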