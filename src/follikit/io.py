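"""Image and mask I/O: PNG/TIFF via imageio, DICOM (read-only) via pydicom.

Conventions: grayscale arrays indexed (row, col), 0-based; mask value 1 marks
the structure.  For DICOM files the PixelSpacing attribute supplies the
mm-per-pixel scale when present.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

DICOM_SUFFIXES = {".dcm", ".dicom"}


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a grayscale image; returns (array, pixel spacing mm or None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in DICOM_SUFFIXES:
        return _read_dicom(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image")
    return np.asarray(arr), None


def _read_dicom(path: Path) -> tuple[np.ndarray, float | None]:
    import pydicom

    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1:
        raise ValueError(f"{path}: multi-frame DICOM not supported")
    arr = ds.pixel_array
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
        spacing = (row_mm + col_mm) / 2.0
    return np.asarray(arr), spacing


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any non-zero pixel is the structure."""
    arr, _ = read_image(path)
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    iio.imwrite(Path(path), ((mask > 0) * 255).astype(np.uint8))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float or uint8 grayscale image as 8-bit PNG."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    iio.imwrite(Path(path), image)
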