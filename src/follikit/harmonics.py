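"""DCT filter banks and harmonic convolution.

A harmonic convolution replaces a learned f x f spatial kernel by a learned
linear combination of the responses to a *fixed* orthonormal 2-D DCT-II filter
bank.  The bank kernel for frequency pair (u, v) evaluated at pixel (i, j) is

    gamma_{u,v}(i, j) = sqrt(b_u / f) * sqrt(b_v / f)
                        * cos(pi * (i + 1/2) * u / f)
                        * cos(pi * (j + 1/2) * v / f),

with b_0 = 1 and b_{u>0} = 2, the normalization that makes the f^2 flattened
kernels an orthonormal set.  The learned weights w[d, n, u, v] combine the
per-frequency responses of every input channel n into output channel d, which
is algebraically identical to an ordinary convolution whose effective kernel
is sum_{u,v} w[d, n, u, v] * gamma_{u,v} -- the implementation exploits this
to run one BLAS-backed convolution instead of f^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class FilterBank:
    """Fixed orthonormal 2-D DCT-II basis of an f x f window.

    Attributes
    ----------
    size:
        Odd kernel side length ``f``.
    kernels:
        Array of shape ``(f, f, f, f)``; ``kernels[u, v]`` is the f x f
        spatial kernel selective for frequency pair ``(u, v)``.
    """

    size: int
    kernels: np.ndarray = field(repr=False)

    def flattened(self) -> np.ndarray:
        """The f^2 x f^2 matrix whose rows are the flattened kernels."""
        f = self.size
        return self.kernels.reshape(f * f, f * f)

    def gram(self) -> np.ndarray:
        m = self.flattened()
        return m @ m.T


def build_filter_bank(f: int) -> FilterBank:
    """Construct the orthonormal DCT-II filter bank of odd size ``f``.

    Raises
    ------
    ValueError
        If ``f`` is not a positive odd integer.
    """
    if not isinstance(f, (int, np.integer)) or f < 1 or f % 2 == 0:
        raise ValueError(f"filter bank size must be a positive odd integer, got {f!r}")
    idx = np.arange(f)
    beta = np.full(f, 2.0)
    beta[0] = 1.0
    # basis[u, i] = sqrt(beta_u / f) * cos(pi * (i + 1/2) * u / f)
    basis = np.sqrt(beta / f)[:, None] * np.cos(
        np.pi * (idx[None, :] + 0.5) * idx[:, None] / f
    )
    kernels = np.einsum("ui,vj->uvij", basis, basis)
    return FilterBank(size=int(f), kernels=kernels)


@dataclass
class HarmonicConvSpec:
    """Learned weights tying a filter bank to channel counts.

    ``weights`` has shape (out_channels, in_channels, f, f), indexed by the
    frequency pair (u, v) in its trailing axes; ``bias`` is per output channel.
    """

    in_channels: int
    out_channels: int
    bank: FilterBank
    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        f = self.bank.size
        expected = (self.out_channels, self.in_channels, f, f)
        if np.shape(self.weights) != expected:
            raise ValueError(
                f"weights shape {np.shape(self.weights)} != expected {expected}"
            )

    def effective_kernel(self) -> np.ndarray:
        """Collapse weights x bank into a standard conv kernel (D, C, f, f)."""
        return np.einsum("dcuv,uvij->dcij", self.weights, self.bank.kernels)


def harmonic_conv(x: np.ndarray, spec: HarmonicConvSpec) -> np.ndarray:
    """Apply a harmonic convolution with 'same' zero padding.

    ``x`` is a rank-4 feature array (batch, channel, height, width).  Output
    channel d is sum over input channels n and frequencies (u, v) of
    ``w[d, n, u, v]`` times the correlation of the (u, v) bank kernel with
    channel n.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected rank-4 input (N, C, H, W), got shape {x.shape}")
    if x.shape[1] != spec.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, spec expects {spec.in_channels}"
        )
    f = spec.bank.size
    if x.shape[2] < f or x.shape[3] < f:
        raise ValueError(f"spatial dims {x.shape[2:]} smaller than kernel {f}")
    kernel = spec.effective_kernel()
    pad = (f - 1) // 2
    out = nn.conv2d(Tensor(x), Tensor(kernel), padding=(pad, pad)).data
    if spec.bias is not None:
        out = out + np.asarray(spec.bias).reshape(1, -1, 1, 1)
    return out


class HarmonicConv2d(nn.Module):
    """Trainable harmonic convolution layer ('same' padding, stride 1).

    The DCT bank is a frozen constant; gradients flow only through the
    combination weights and bias.
    """

    def __init__(self, in_channels: int, out_channels: int, f: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.bank = build_filter_bank(f)
        self.f = f
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * f * f
        self.weight = nn.kaiming_weight(
            rng, (out_channels, in_channels, f, f), fan_in
        )
        self.bias = (
            Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        )
        # flattened bank matrix used to collapse weights into a conv kernel
        self._bank_matrix = Tensor(self.bank.flattened())  # (f^2, f^2), frozen

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"input has {x.data.shape[1]} channels, layer expects "
                f"{self.in_channels}"
            )
        f = self.f
        d, c = self.out_channels, self.in_channels
        # effective kernel = weights (in uv basis) projected through the bank
        kernel = (self.weight.reshape(d * c, f * f) @ self._bank_matrix).reshape(
            d, c, f, f
        )
        pad = (f - 1) // 2
        return nn.conv2d(x, kernel, self.bias, padding=(pad, pad))

    def spec(self) -> HarmonicConvSpec:
        return HarmonicConvSpec(
            in_channels=self.in_channels,
            out_channels=self.out_channels,
            bank=self.bank,
            weights=self.weight.data.copy(),
            bias=None if self.bias is None else self.bias.data.copy(),
        )
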