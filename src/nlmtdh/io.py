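"""Reading and writing 8-bit grayscale images (PNG, TIFF, PGM) and masks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._util import DEFAULT_LEVELS, validate_gray_image
from .exceptions import InputError

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path: str | Path, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Read a single-channel gray-level image.

    Multi-channel inputs are rejected rather than silently converted."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise InputError(
            f"{path}: expected a single-channel image, got shape {arr.shape}; "
            "convert to grayscale before loading"
        )
    return validate_gray_image(arr, levels)


def write_image(path: str | Path, image: np.ndarray, levels: int = DEFAULT_LEVELS) -> None:
    """Write a gray-level image as 8-bit."""
    img = validate_gray_image(image, levels)
    iio.imwrite(path, img.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: 0 is background, any nonzero value foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise InputError(f"{path}: expected a single-channel mask, got shape {arr.shape}")
    return arr != 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit image with foreground = 255."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {m.shape}")
    iio.imwrite(path, (m.astype(bool) * np.uint8(255)))
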