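"""Training loop, preprocessing and augmentation.

The recipe follows the published hyperparameters: images resized to a square
input (default 384 px) and scaled to [0, 1]; augmentation by random rotations
up to +/-15 degrees and horizontal flips; Adam with beta1 = 0.5, beta2 = 0.999
at learning rate 2e-4, batch size 4, up to 50 epochs; the learning rate is
multiplied by a decay factor (default 0.5) whenever the validation Dice fails
to improve for two consecutive epochs.  The best-validation-Dice weights are
restored at the end.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as nd_rotate
from skimage.transform import resize

from .losses import LossConfig, combined_loss
from .metrics import segmentation_metrics
from .nn import Adam, Tensor
from .network import HarmonicAttentionUNet


@dataclass
class TrainConfig:
    input_size: int = 384
    lr: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 4
    max_rotation_deg: float = 15.0
    rotation_prob: float = 0.5
    flip_prob: float = 0.5
    plateau_patience: int = 2
    decay_factor: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        for name in ("input_size", "lr", "epochs", "batch_size",
                     "plateau_patience", "decay_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_size % 16:
            raise ValueError("input_size must be divisible by 16")


def preprocess(image: np.ndarray, input_size: int = 384,
               is_mask: bool = False) -> np.ndarray:
    """Resize to (input_size, input_size) and scale intensities to [0, 1].

    Images are resized bilinearly; masks use nearest neighbour so labels stay
    binary.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.max() > 1.0:
        image = image / 255.0
    if image.shape != (input_size, input_size):
        image = resize(image, (input_size, input_size), order=0 if is_mask else 1,
                       anti_aliasing=False, preserve_range=True)
    if is_mask:
        image = (image > 0.5).astype(np.float64)
    return image


def rotate_pair(image: np.ndarray, mask: np.ndarray,
                angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) by the same angle.

    Reflective borders keep the texture statistics of the frame intact
    (zero-filled corners would leak into batch normalization).
    """
    if angle_deg == 0.0:
        return image, mask
    img = nd_rotate(image, angle_deg, reshape=False, order=1, mode="reflect")
    msk = nd_rotate(mask, angle_deg, reshape=False, order=0, mode="reflect")
    return img, (msk > 0.5).astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator | int,
            max_rotation_deg: float = 15.0,
            rotation_prob: float = 0.5,
            flip_prob: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Identical random rotation + horizontal flip applied to both arrays.

    Each transform fires with its own probability, so un-resampled images
    remain part of the training distribution (rotation interpolation smooths
    the speckle texture).
    """
    if np.shape(image) != np.shape(mask):
        raise ValueError("image and mask shapes differ")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if max_rotation_deg > 0 and rng.random() < rotation_prob:
        angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
        image, mask = rotate_pair(image, mask, angle)
    if rng.random() < flip_prob:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    return image, mask


class PlateauScheduler:
    """Multiply the optimizer lr by `factor` after `patience` consecutive
    epochs without improvement of the monitored score (higher is better)."""

    def __init__(self, optimizer: Adam, patience: int = 2, factor: float = 0.5,
                 min_delta: float = 0.0):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = -np.inf
        self.stale = 0
        self.n_decays = 0

    def step(self, score: float) -> bool:
        """Record one epoch's score; returns True if a decay fired."""
        if score > self.best + self.min_delta:
            self.best = score
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            self.n_decays += 1
            return True
        return False


def _validation_dice(model: HarmonicAttentionUNet,
                     pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    model.eval()
    scores = []
    for image, mask in pairs:
        prob = model(Tensor(image[None, None])).data[0, 0]
        pred = (prob > 0.5).astype(np.uint8)
        scores.append(segmentation_metrics(mask.astype(np.uint8), pred)["dice"])
    model.train()
    return float(np.mean(scores))


def train(model: HarmonicAttentionUNet,
          train_pairs: list[tuple[np.ndarray, np.ndarray]],
          val_pairs: list[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig,
          log_fn=None) -> tuple[HarmonicAttentionUNet, pd.DataFrame]:
    """Train on (image, mask) pairs; returns (best model, per-epoch log).

    Pairs must be preprocessed already (square [0, 1] arrays of the same
    size divisible by 16).  The returned model carries the weights of the
    epoch with the best validation Dice.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    if not val_pairs:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr,
                     betas=(cfg.adam_beta1, cfg.adam_beta2))
    scheduler = PlateauScheduler(optimizer, patience=cfg.plateau_patience,
                                 factor=cfg.decay_factor)
    best_dice = -np.inf
    best_state = None
    rows = []
    model.train()
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            images, masks = [], []
            for i in batch_idx:
                img, msk = augment(
                    train_pairs[i][0], train_pairs[i][1], rng,
                    max_rotation_deg=cfg.max_rotation_deg,
                    rotation_prob=cfg.rotation_prob,
                    flip_prob=cfg.flip_prob,
                )
                images.append(img)
                masks.append(msk)
            x = Tensor(np.stack(images)[:, None])
            y = Tensor(np.stack(masks)[:, None].astype(np.float64))
            prob = model(x)
            loss = combined_loss(y, prob, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_dice = _validation_dice(model, val_pairs)
        decayed = scheduler.step(val_dice)
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = copy.deepcopy(model.state_dict())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_dice": val_dice, "lr": optimizer.lr,
                     "lr_decayed": decayed})
        if log_fn is not None:
            log_fn(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                   f"val Dice {val_dice:.4f}  lr {optimizer.lr:.2e}"
                   + ("  [lr decayed]" if decayed else ""))
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(rows)


def overfit_single(model: HarmonicAttentionUNet, image: np.ndarray,
                   mask: np.ndarray, iterations: int = 200,
                   cfg: TrainConfig | None = None) -> float:
    """Fit one (image, mask) pair repeatedly; returns the final training Dice.

    Sanity oracle: a correctly wired network and loss should memorize a single
    sample almost perfectly.
    """
    cfg = cfg or TrainConfig(input_size=image.shape[0])
    optimizer = Adam(model.parameters(), lr=cfg.lr,
                     betas=(cfg.adam_beta1, cfg.adam_beta2))
    x = Tensor(image[None, None].astype(np.float64))
    y = Tensor(mask[None, None].astype(np.float64))
    model.train()
    for _ in range(iterations):
        prob = model(x)
        loss = combined_loss(y, prob, cfg.loss)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    model.eval()
    pred = (model(x).data[0, 0] > 0.5).astype(np.uint8)
    return segmentation_metrics(mask.astype(np.uint8), pred)["dice"]
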