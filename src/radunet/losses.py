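"""Training losses: binary cross-entropy, smoothed Dice, and their sum.

Lesion pixels are rare, so plain BCE under-weights the foreground; the
Dice term rewards overlap directly and counteracts the imbalance, while
BCE keeps gradients stable.  The combined loss is simply

    L(y, yhat) = L_BCE(y, yhat) + L_Dice(y, yhat)

with L_BCE the pixel-mean cross-entropy and

    L_Dice = 1 - (2 * sum(y*yhat) + s) / (sum(y) + sum(yhat) + s)

using symmetric smoothing s = 1 in numerator and denominator, which
makes the loss exactly 0 for any perfect match, including the all-
background case, and keeps it differentiable everywhere.

Each loss accepts either numpy arrays (returning a float) or autodiff
Tensors (returning a graph node for backprop).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, clip, log, mul, reduce_mean, reduce_sum

#: probability clamp applied before the logarithm in BCE
EPS = 1e-7
#: Dice smoothing constant (numerator and denominator)
DICE_SMOOTH = 1.0


def _check_binary(y: np.ndarray) -> None:
    if not np.isin(y, (0, 1)).all():
        raise ValueError("target mask must contain only 0 and 1")


def bce_loss(y, y_pred):
    """Mean binary cross-entropy: -(y log p + (1-y) log(1-p)), averaged over pixels."""
    if isinstance(y_pred, Tensor):
        yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float32))
        _check_binary(yt.data)
        p = clip(y_pred, EPS, 1.0 - EPS)
        term = mul(yt, log(p)) + mul(1.0 - yt, log(1.0 - p))
        return reduce_mean(-term)
    y = np.asarray(y, dtype=np.float64)
    _check_binary(y)
    p = np.clip(np.asarray(y_pred, dtype=np.float64), EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(y, y_pred, smooth: float = DICE_SMOOTH):
    """Smoothed soft Dice loss, in [0, 1); 0 for any exact match."""
    if isinstance(y_pred, Tensor):
        yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float32))
        if yt.shape != y_pred.shape:
            raise ValueError(f"shape mismatch: {yt.shape} vs {y_pred.shape}")
        inter = reduce_sum(mul(yt, y_pred))
        total = reduce_sum(yt) + reduce_sum(y_pred)
        return 1.0 - (2.0 * inter + smooth) / (total + smooth)
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    inter = float((y * p).sum())
    total = float(y.sum() + p.sum())
    return 1.0 - (2.0 * inter + smooth) / (total + smooth)


def combined_loss(y, y_pred):
    """BCE + Dice, the training objective."""
    return bce_loss(y, y_pred) + dice_loss(y, y_pred)
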