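"""Shared low-level helpers: validation, quantization, exact box sums."""

from __future__ import annotations

import numpy as np

from .exceptions import InputError

DEFAULT_LEVELS = 256


def validate_gray_image(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Check that *image* is a 2-D integer grid with values in [0, levels-1].

    Returns the image as a contiguous integer array. Raises
    :class:`~nlmtdh.exceptions.InputError` otherwise.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise InputError(
            f"expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise InputError("image is empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise InputError(f"gray levels must be integers, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise InputError(
            f"gray levels must lie in [0, {levels - 1}], "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    return np.ascontiguousarray(arr, dtype=np.int64)


def quantize(values: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Round half-up to the nearest integer and clip to [0, levels-1]."""
    return np.clip(np.floor(np.asarray(values, dtype=np.float64) + 0.5), 0, levels - 1).astype(np.int64)


def box_sum_valid(arr: np.ndarray, size: int) -> np.ndarray:
    """Exact sliding-window sum of a *size* x *size* box, 'valid' positions only.

    Output shape is (H - size + 1, W - size + 1). Uses a summed-area table,
    which is exact up to float64 accumulation error.
    """
    c = np.cumsum(np.cumsum(np.asarray(arr, dtype=np.float64), axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]
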