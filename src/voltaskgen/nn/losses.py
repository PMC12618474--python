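"""Contrast-regularized reconstructive (CR-R) loss.

For a mini-batch of N subjects with actual maps ``x_i`` and predictions
``x_hat_i``, with ``d(a, b)`` the mean squared error over in-mask voxels of
all selected contrast channels:

* reconstructive term  ``L_R = (1/N) sum_i d(x_i, x_hat_i)``
* contrastive term     ``L_C = mean over ordered pairs j != i of d(x_j, x_hat_i)``
* combined             ``L = L_R + alpha * min(L_R - L_C + lambda, 0)``

``d`` is asymmetric in the roles of prediction and actual map, so ``L_C``
averages over all ``N(N-1)`` ordered cross-subject pairs.  The combined
form above is the printed hinge ("min_as_printed"); the alternative
"max_hinge" mode, ``L_R + alpha * max(L_R - L_C + lambda, 0)``, penalizes a
contrastive term that fails to exceed the reconstruction error by the
margin lambda and is provided because that matches the stated intent of the
margin.  With ``alpha = 0`` both reduce to plain masked MSE; with ``N = 1``
there are no cross pairs and the loss falls back to ``L_R`` alone.

Defaults: ``lambda = 1``, ``alpha = 0.25``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

__all__ = [
    "LossConfig",
    "reconstructive_loss",
    "contrastive_loss",
    "crr_loss",
    "crr_loss_with_grad",
]


@dataclass(frozen=True)
class LossConfig:
    """CR-R hyperparameters: margin (loss units), weight (dimensionless)."""

    lam: float = 1.0
    alpha: float = 0.25
    hinge_mode: Literal["min_as_printed", "max_hinge"] = "min_as_printed"

    def __post_init__(self):
        if self.lam < 0 or self.alpha < 0:
            raise ValueError("lambda and alpha must be non-negative")
        if self.hinge_mode not in ("min_as_printed", "max_hinge"):
            raise ValueError(f"unknown hinge_mode {self.hinge_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _masked(batch: np.ndarray, mask: np.ndarray,
            channels: np.ndarray | None) -> np.ndarray:
    """Flatten (N, C, *dims) to (N, M) over in-mask voxels of selected channels."""
    batch = np.asarray(batch)
    if batch.ndim < 3:
        raise ValueError("batch must be (N, C, *spatial)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != batch.shape[2:]:
        raise ValueError(f"mask shape {mask.shape} != spatial dims {batch.shape[2:]}")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = batch[:, :, mask]  # (N, C, n_mask)
    if channels is not None:
        vals = vals[:, channels]
    return vals.reshape(vals.shape[0], -1)


def reconstructive_loss(pred_batch, actual_batch, mask, channels=None) -> float:
    """L_R: mean over subjects of the in-mask MSE between actual and predicted."""
    P = _masked(pred_batch, mask, channels)
    A = _masked(actual_batch, mask, channels)
    return float(np.mean((P - A) ** 2))


def contrastive_loss(pred_batch, actual_batch, mask, channels=None) -> float:
    """L_C: mean masked MSE over all ordered cross-subject pairs (j != i)."""
    P = _masked(pred_batch, mask, channels)
    A = _masked(actual_batch, mask, channels)
    N, M = P.shape
    if N < 2:
        raise ValueError("contrastive loss needs at least 2 subjects in the batch")
    # cross[i, j] = d(x_j, x_hat_i)
    p2 = np.sum(P * P, axis=1)
    a2 = np.sum(A * A, axis=1)
    cross = (p2[:, None] + a2[None, :] - 2.0 * P @ A.T) / M
    total = cross.sum() - np.trace(cross)
    return float(total / (N * (N - 1)))


def crr_loss(pred_batch, actual_batch, mask, config: LossConfig = LossConfig(),
             channels=None) -> float:
    """The combined CR-R loss (falls back to L_R for a single-subject batch)."""
    loss, _, _ = crr_loss_with_grad(pred_batch, actual_batch, mask, config,
                                    channels=channels, need_grad=False)
    return loss


def crr_loss_with_grad(pred_batch, actual_batch, mask,
                       config: LossConfig = LossConfig(), channels=None,
                       need_grad: bool = True):
    """CR-R loss, its gradient w.r.t. the predictions, and its components.

    Returns ``(loss, grad, parts)`` where *grad* has the shape of
    *pred_batch* (exactly zero outside the mask and on unselected channels)
    and *parts* holds ``L_R``, ``L_C`` (NaN for N = 1) and the hinge state.
    """
    pred_batch = np.asarray(pred_batch)
    mask_b = np.asarray(mask, dtype=bool)
    ch = None if channels is None else np.asarray(channels)
    P = _masked(pred_batch, mask_b, ch)
    A = _masked(actual_batch, mask_b, ch)
    N, M = P.shape

    diff = P - A
    l_r = float(np.mean(diff**2))
    grad_flat = None

    if N < 2:
        loss, l_c, active = l_r, float("nan"), False
        if need_grad:
            grad_flat = 2.0 * diff / (N * M)
    else:
        p2 = np.sum(P * P, axis=1)
        a2 = np.sum(A * A, axis=1)
        cross = (p2[:, None] + a2[None, :] - 2.0 * P @ A.T) / M
        l_c = float((cross.sum() - np.trace(cross)) / (N * (N - 1)))
        z = l_r - l_c + config.lam
        if config.hinge_mode == "min_as_printed":
            active = z < 0.0
            loss = l_r + config.alpha * min(z, 0.0)
        else:
            active = z > 0.0
            loss = l_r + config.alpha * max(z, 0.0)
        if need_grad:
            d_lr = 2.0 * diff / (N * M)
            s = config.alpha if active else 0.0
            if s:
                # dL_C/dP_i = 2((N-1) P_i - (sum_j A_j - A_i)) / (N(N-1)M)
                others = A.sum(axis=0)[None, :] - A
                d_lc = 2.0 * ((N - 1) * P - others) / (N * (N - 1) * M)
                grad_flat = (1.0 + s) * d_lr - s * d_lc
            else:
                grad_flat = d_lr

    grad = None
    if need_grad:
        grad = np.zeros_like(pred_batch, dtype=np.float64)
        n_sel = P.shape[1] // mask_b.sum()
        g = grad_flat.reshape(N, n_sel, -1)
        if ch is None:
            grad[:, :, mask_b] = g
        else:
            tmp = np.zeros((N, pred_batch.shape[1], int(mask_b.sum())))
            tmp[:, ch] = g
            grad[:, :, mask_b] = tmp

    parts = {"L_R": l_r, "L_C": l_c, "hinge_active": bool(active)}
    return float(loss), grad, parts
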