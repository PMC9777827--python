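"""Harmonic channel attention.

The block is a squeeze-and-excitation style channel gate: global average
pooling collapses each channel to one statistic, two 1x1 harmonic convolutions
(a bottleneck of ratio r with ReLU between, sigmoid after) turn the statistics
into per-channel attention values in (0, 1), the input is re-scaled channel-wise
by those values, and a residual connection adds the input back:

    T' = GAP(T);  a = sigmoid(W1 * relu(W0 * T'));  O = a (.) T + T

A 1x1 DCT basis is the scalar 1, so the two 1x1 harmonic convolutions are
learned channel mixings; they are still routed through the harmonic layer for
uniformity with the rest of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .harmonics import HarmonicConv2d
from .nn import Tensor


def effective_reduction(channels: int, reduction: int) -> int:
    """Largest divisor of `channels` that is <= min(reduction, channels // 4).

    Keeps the bottleneck at least 4 channels wide (or 1 for tiny layers) and
    guarantees divisibility.
    """
    cap = max(1, min(reduction, channels // 4))
    for r in range(cap, 0, -1):
        if channels % r == 0:
            return r
    return 1


@dataclass
class HABlockSpec:
    """Plain-array description of a harmonic attention block (for oracles)."""

    channels: int
    reduction: int
    w0: np.ndarray  # (C/r, C)
    b0: np.ndarray  # (C/r,)
    w1: np.ndarray  # (C, C/r)
    b1: np.ndarray  # (C,)

    def __post_init__(self):
        if self.channels % self.reduction != 0:
            raise ValueError(
                f"channels {self.channels} not divisible by reduction "
                f"{self.reduction}"
            )


class HarmonicAttention(nn.Module):
    """Channel attention with residual add; preserves input shape."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16, bias: bool = True):
        super().__init__()
        self.channels = channels
        self.reduction = effective_reduction(channels, reduction)
        hidden = channels // self.reduction
        self.squeeze = HarmonicConv2d(channels, hidden, f=1, rng=rng, bias=bias)
        self.excite = HarmonicConv2d(hidden, channels, f=1, rng=rng, bias=bias)

    def forward(self, t: Tensor) -> Tensor:
        if t.data.shape[1] != self.channels:
            raise ValueError(
                f"input has {t.data.shape[1]} channels, block expects "
                f"{self.channels}"
            )
        pooled = t.mean(axis=(2, 3), keepdims=True)          # (N, C, 1, 1)
        attn = self.excite(self.squeeze(pooled).relu()).sigmoid()
        return t * attn + t

    def spec(self) -> HABlockSpec:
        return HABlockSpec(
            channels=self.channels,
            reduction=self.reduction,
            w0=self.squeeze.weight.data[:, :, 0, 0].copy(),
            b0=self.squeeze.bias.data.copy(),
            w1=self.excite.weight.data[:, :, 0, 0].copy(),
            b1=self.excite.bias.data.copy(),
        )


def harmonic_attention_reference(t: np.ndarray, spec: HABlockSpec) -> np.ndarray:
    """Loop-based direct evaluation of the attention equations (test oracle)."""
    t = np.asarray(t, dtype=np.float64)
    n, c, h, w = t.shape
    out = np.empty_like(t)
    for img in range(n):
        pooled = np.array([t[img, ch].mean() for ch in range(c)])
        hid = np.maximum(spec.w0 @ pooled + spec.b0, 0.0)
        attn = 1.0 / (1.0 + np.exp(-(spec.w1 @ hid + spec.b1)))
        for ch in range(c):
            out[img, ch] = t[img, ch] * attn[ch] + t[img, ch]
    return out
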