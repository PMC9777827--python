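"""Training objectives: BCE, focal, soft-Dice, and weighted combinations.

The default objective is BCE + eta * focal with eta = 0.6 and focal exponent
gamma = 2.  All losses are pixel means; predictions are clipped to
[eps, 1 - eps] with eps = 1e-7 before any logarithm.  Each loss accepts plain
numpy arrays (returning a float) or autodiff Tensors (returning a scalar
Tensor through which gradients flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

EPS = 1e-7

VARIANTS = ("bce", "dice", "bce+dice", "bce+focal")


@dataclass
class LossConfig:
    eta: float = 0.6          # weight of the focal term in bce+focal
    gamma_focal: float = 2.0  # focal down-weighting exponent
    variant: str = "bce+focal"

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.gamma_focal < 0:
            raise ValueError("gamma_focal must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown loss variant {self.variant!r}; "
                             f"choose from {VARIANTS}")


def _prepare(y, yhat):
    wrap = isinstance(y, Tensor) or isinstance(yhat, Tensor)
    y = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    yhat = yhat if isinstance(yhat, Tensor) else Tensor(
        np.asarray(yhat, dtype=np.float64)
    )
    if y.data.shape != yhat.data.shape:
        raise ValueError(
            f"target shape {y.data.shape} != prediction shape {yhat.data.shape}"
        )
    return y, yhat.clip(EPS, 1.0 - EPS), wrap


def _ret(value: Tensor, wrap: bool):
    return value if wrap else float(value.data)


def bce_loss(y, yhat):
    """Mean binary cross-entropy: -y log(p) - (1-y) log(1-p)."""
    y, p, wrap = _prepare(y, yhat)
    loss = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return _ret(loss.mean(), wrap)


def focal_loss(y, yhat, gamma: float = 2.0):
    """Mean focal loss: -y (1-p)^g log(p) - (1-y) p^g log(1-p).

    Reduces exactly to BCE at gamma = 0.
    """
    y, p, wrap = _prepare(y, yhat)
    loss = -(y * (1.0 - p).pow(gamma) * p.log()
             + (1.0 - y) * p.pow(gamma) * (1.0 - p).log())
    return _ret(loss.mean(), wrap)


def dice_loss(y, yhat, smooth: float = 1.0):
    """1 - soft Dice = 1 - (2|y.p| + s) / (|y| + |p| + s)."""
    y, p, wrap = _prepare(y, yhat)
    inter = (y * p).sum()
    total = y.sum() + p.sum()
    dice = (2.0 * inter + smooth) * (total + smooth).pow(-1.0)
    return _ret(1.0 - dice, wrap)


def combined_loss(y, yhat, cfg: LossConfig | None = None):
    """Loss selected by ``cfg.variant``; default BCE + eta * focal."""
    cfg = cfg or LossConfig()
    if cfg.variant == "bce":
        return bce_loss(y, yhat)
    if cfg.variant == "dice":
        return dice_loss(y, yhat)
    if cfg.variant == "bce+dice":
        return bce_loss(y, yhat) + dice_loss(y, yhat)
    # bce + eta * focal
    return bce_loss(y, yhat) + cfg.eta * focal_loss(y, yhat, cfg.gamma_focal)
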