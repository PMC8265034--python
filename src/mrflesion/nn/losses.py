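"""Training losses: MSE, MAE, log-cosh (LCL) and soft dice (DICE).

All losses average over every element of the batch; for multi-channel
targets the channels enter with equal (unweighted) weight, which is why the
quantitative channels must be normalized to O(1) before training.  The dice
loss is computed per channel on the soft predictions and averaged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compute_loss", "loss_and_grad", "LOSS_NAMES"]

LOSS_NAMES = ("MSE", "MAE", "LCL", "DICE")
_DICE_EPS = 1e-6


def loss_and_grad(loss_name: str, predicted: np.ndarray, target: np.ndarray):
    """Return (scalar loss, gradient w.r.t. predicted)."""
    # float64 so loss values are exact at identity and gradients checkable
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs target {t.shape}")
    d = p - t
    n = d.size
    if loss_name == "MSE":
        return float(np.mean(d**2)), (2.0 / n) * d
    if loss_name == "MAE":
        return float(np.mean(np.abs(d))), np.sign(d) / n
    if loss_name == "LCL":
        # log cosh computed via |x| + log1p(exp(-2|x|)) - log 2 for stability
        a = np.abs(d)
        val = float(np.mean(a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)))
        return val, np.tanh(d) / n
    if loss_name == "DICE":
        # per channel over the batch: channel axis 1 of (N, C, ...) input,
        # or the whole array when unbatched
        if p.ndim >= 2:
            axes = (0,) + tuple(range(2, p.ndim))
            inter = np.sum(p * t, axis=axes)
            sums = np.sum(p, axis=axes) + np.sum(t, axis=axes)
        else:
            inter = np.sum(p * t, keepdims=True)
            sums = np.array([np.sum(p) + np.sum(t)])
        dice = (2.0 * inter + _DICE_EPS) / (sums + _DICE_EPS)
        val = float(np.mean(1.0 - dice))
        nch = dice.size
        shape = [1] * p.ndim
        if p.ndim >= 2:
            shape[1] = nch
        inter_b = inter.reshape(shape)
        sums_b = sums.reshape(shape)
        grad = -(2.0 * t * (sums_b + _DICE_EPS) - (2.0 * inter_b + _DICE_EPS)) / (
            (sums_b + _DICE_EPS) ** 2
        )
        return val, grad / nch
    raise ValueError(f"unknown loss {loss_name!r}; choose from {LOSS_NAMES}")


def compute_loss(loss_name: str, predicted: np.ndarray, target: np.ndarray) -> float:
    """Scalar loss value (see :func:`loss_and_grad`)."""
    return loss_and_grad(loss_name, predicted, target)[0]
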