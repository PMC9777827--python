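"""Harmonic-attention U-Net for ovary / follicle segmentation.

Encoder-decoder with five levels and skip connections.  Every standard spatial
convolution of a U-Net encoder is replaced by a harmonic convolution (a learned
combination of fixed DCT filter-bank responses); the first two levels add an
ERFNet-style 1-D kernel factorization (3x1 then 1x3 convs), and levels 2-5 end
with a harmonic channel-attention block.  2x2 max pooling halves resolution
between encoder levels; the decoder mirrors the encoder with 2x2 stride-2
transposed convolutions, concatenating the same-level encoder features, and
ends in a 1x1 convolution with a sigmoid head.  Setting ``use_ha=False``
replaces every attention block with the identity, giving the plain
harmonic-convolution baseline used for ablations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .attention import HarmonicAttention
from .harmonics import HarmonicConv2d
from .nn import Tensor


@dataclass
class NetworkConfig:
    base_width: int = 64
    depth: int = 5
    f: int = 3
    in_channels: int = 1
    out_channels: int = 1
    ha_reduction: int = 16
    use_ha: bool = True
    # initial foreground probability of the sigmoid head; 0.5 is neutral,
    # rare-foreground targets (follicles) should use their coverage rate
    head_prior: float = 0.5
    seed: int = 0

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** lvl for lvl in range(self.depth)]

    @property
    def divisor(self) -> int:
        """Spatial dims must be divisible by this (2^(depth-1))."""
        return 2 ** (self.depth - 1)


class _HConvBNReLU(nn.Module):
    def __init__(self, cin: int, cout: int, f: int, rng):
        super().__init__()
        self.conv = HarmonicConv2d(cin, cout, f=f, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _FactorizedPair(nn.Module):
    """Consecutive 3x1 and 1x3 convolutions, each with BN + ReLU."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv_v = nn.Conv2d(channels, channels, (3, 1), rng)
        self.bn_v = nn.BatchNorm2d(channels)
        self.conv_h = nn.Conv2d(channels, channels, (1, 3), rng)
        self.bn_h = nn.BatchNorm2d(channels)

    def forward(self, x):
        x = self.bn_v(self.conv_v(x)).relu()
        return self.bn_h(self.conv_h(x)).relu()


class _Identity(nn.Module):
    def forward(self, x):
        return x


class HarmonicAttentionUNet(nn.Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        if cfg.depth != 5:
            raise ValueError("the architecture is defined for depth 5")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.widths

        def ha(channels):
            if not cfg.use_ha:
                return _Identity()
            return HarmonicAttention(channels, rng, reduction=cfg.ha_reduction)

        # encoder
        self.enc1 = nn.Sequential(
            _HConvBNReLU(cfg.in_channels, w[0], cfg.f, rng), _FactorizedPair(w[0], rng)
        )
        self.enc2 = nn.Sequential(
            _HConvBNReLU(w[0], w[1], cfg.f, rng), _FactorizedPair(w[1], rng), ha(w[1])
        )
        self.enc3 = nn.Sequential(_HConvBNReLU(w[1], w[2], cfg.f, rng), ha(w[2]))
        self.enc4 = nn.Sequential(_HConvBNReLU(w[2], w[3], cfg.f, rng), ha(w[3]))
        self.enc5 = nn.Sequential(_HConvBNReLU(w[3], w[4], cfg.f, rng), ha(w[4]))

        # decoder (mirrors the encoder; attention where the encoder had it)
        self.up4 = nn.ConvTranspose2x2(w[4], w[3], rng)
        self.dec4 = nn.Sequential(_HConvBNReLU(2 * w[3], w[3], cfg.f, rng), ha(w[3]))
        self.up3 = nn.ConvTranspose2x2(w[3], w[2], rng)
        self.dec3 = nn.Sequential(_HConvBNReLU(2 * w[2], w[2], cfg.f, rng), ha(w[2]))
        self.up2 = nn.ConvTranspose2x2(w[2], w[1], rng)
        self.dec2 = nn.Sequential(
            _HConvBNReLU(2 * w[1], w[1], cfg.f, rng), _FactorizedPair(w[1], rng),
            ha(w[1])
        )
        self.up1 = nn.ConvTranspose2x2(w[1], w[0], rng)
        self.dec1 = nn.Sequential(
            _HConvBNReLU(2 * w[0], w[0], cfg.f, rng), _FactorizedPair(w[0], rng)
        )

        self.head = nn.Conv2d(w[0], cfg.out_channels, (1, 1), rng, padding=(0, 0))
        # prior-probability bias init: the sigmoid head starts near the
        # background rate instead of 0.5, the standard pairing with focal loss
        self.head.bias.data[:] = np.log(cfg.head_prior / (1.0 - cfg.head_prior))

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        n, c, h, w = x.data.shape
        div = self.cfg.divisor
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims ({h}, {w}) must be divisible by {div}"
            )
        e1 = self.enc1(x)
        e2 = self.enc2(nn.max_pool2x2(e1))
        e3 = self.enc3(nn.max_pool2x2(e2))
        e4 = self.enc4(nn.max_pool2x2(e3))
        e5 = self.enc5(nn.max_pool2x2(e4))
        d4 = self.dec4(nn.concat([self.up4(e5), e4], axis=1))
        d3 = self.dec3(nn.concat([self.up3(d4), e3], axis=1))
        d2 = self.dec2(nn.concat([self.up2(d3), e2], axis=1))
        d1 = self.dec1(nn.concat([self.up1(d2), e1], axis=1))
        return self.head(d1).sigmoid()


def build_network(cfg: NetworkConfig) -> HarmonicAttentionUNet:
    return HarmonicAttentionUNet(cfg)


def predict_mask(model: HarmonicAttentionUNet, image: np.ndarray,
                 input_size: int | None = None, threshold: float = 0.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Segment one grayscale image; returns (binary mask, probability map).

    The image is scaled to [0, 1], resized to ``input_size`` (bilinear) if
    given, run through the model in evaluation mode, thresholded at
    ``threshold``, and the mask is resized back to the original resolution
    (nearest neighbour, so it stays binary).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    orig_shape = image.shape
    if image.max() > 1.0:
        image = image / 255.0
    if input_size is not None and orig_shape != (input_size, input_size):
        image = resize(image, (input_size, input_size), order=1,
                       anti_aliasing=False, preserve_range=True)
    was_training = model.training
    model.eval()
    prob = model(Tensor(image[None, None])).data[0, 0]
    if was_training:
        model.train()
    mask = (prob > threshold).astype(np.uint8)
    if mask.shape != orig_shape:
        mask = resize(mask, orig_shape, order=0, anti_aliasing=False,
                      preserve_range=True).astype(np.uint8)
    return mask, prob


def save_checkpoint(model: HarmonicAttentionUNet, path: str | Path) -> None:
    """Save weights (npz) plus the config (json sidecar)."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path, **state)
    cfg_path = path.with_suffix(".json")
    cfg_path.write_text(json.dumps(asdict(model.cfg), indent=2))


def load_checkpoint(path: str | Path) -> HarmonicAttentionUNet:
    path = Path(path)
    cfg = NetworkConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = HarmonicAttentionUNet(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.load_state_dict(dict(data))
    return model
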