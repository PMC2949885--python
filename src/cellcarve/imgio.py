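"""Image reading/writing with normalization to 8-bit RGB."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["load_image", "save_image"]


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/BMP as H x W x 3 uint8.

    Grayscale is promoted by channel replication, alpha is dropped with a
    warning, and 16-bit samples are rescaled by 1/257.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit image (RGB or grayscale)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
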