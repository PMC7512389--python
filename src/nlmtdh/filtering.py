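"""Non-local means (NLM) filtering.

The NLM filter replaces each pixel by a weighted average of other pixels,
with weights decaying in the squared Euclidean distance between the square
gray-level patches surrounding the two pixels:

    Y(i) = sum_j w(i, j) X(j),
    w(i, j) = exp(-||X(N_i) - X(N_j)||^2 / (h^2 sigma^2)) / Z(i),

where N_k is the (2r+1) x (2r+1) patch centred at pixel k, h is the filtering
degree, sigma the Gaussian-kernel standard deviation, and Z(i) normalizes the
weights to sum to one. Because similar patches can occur anywhere in the
image, the average carries spatial structure that a purely local mean loses;
the filtered image serves as the second coordinate of the joint gray-level
histogram used for threshold selection.

Patch distance is the plain sum of squared gray-level differences over the
patch; no per-offset Gaussian weighting is applied inside the patch, and the
self term j = i participates like any other candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

from ._util import DEFAULT_LEVELS, box_sum_valid, quantize, validate_gray_image
from .exceptions import ParameterError

__all__ = ["NLMParams", "nlm_weights", "nlm_filter", "WeightVector"]

_PAD_MODES = ("reflect", "edge")


@dataclass(frozen=True)
class NLMParams:
    """Parameters of the non-local means filter.

    Parameters
    ----------
    patch_radius
        Half-width r of the square comparison patch; the patch side is 2r+1.
    search_radius
        Chebyshev radius of the window of candidate pixels j averaged for
        each pixel i, or ``"full"`` to average over every pixel of the image
        (the literal definition; quadratic in the pixel count, so a windowed
        search is the practical default).
    h
        Filtering degree; larger h flattens the weights and smooths more.
    sigma
        Standard deviation of the Gaussian kernel entering the weight
        denominator h^2 sigma^2 multiplicatively with h.
    pad_mode
        Border handling when extracting patches: ``"reflect"`` (mirror
        without repeating the edge sample) or ``"edge"`` (repeat it).
    """

    patch_radius: int = 2
    search_radius: Union[int, str] = 10
    h: float = 10.0
    sigma: float = 1.0
    pad_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.patch_radius < 0 or int(self.patch_radius) != self.patch_radius:
            raise ParameterError(f"patch_radius must be a non-negative integer, got {self.patch_radius}")
        if self.search_radius != "full" and (
            not isinstance(self.search_radius, (int, np.integer)) or self.search_radius < 1
        ):
            raise ParameterError(
                f"search_radius must be a positive integer or 'full', got {self.search_radius!r}"
            )
        if not self.h > 0:
            raise ParameterError(f"h must be positive, got {self.h}")
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if self.pad_mode not in _PAD_MODES:
            raise ParameterError(f"pad_mode must be one of {_PAD_MODES}, got {self.pad_mode!r}")


class WeightVector(NamedTuple):
    """Normalized NLM weights for one pixel, with candidate coordinates."""

    weights: np.ndarray  # (K,) nonnegative, sums to 1
    indices: np.ndarray  # (K, 2) row/col of each candidate pixel, row-major order


def _search_bounds(params: NLMParams, shape: tuple[int, int]) -> tuple[int, int]:
    if params.search_radius == "full":
        return shape[0] - 1, shape[1] - 1
    s = int(params.search_radius)
    return s, s


def nlm_weights(
    image: np.ndarray,
    i: tuple[int, int],
    params: NLMParams = NLMParams(),
    levels: int = DEFAULT_LEVELS,
) -> WeightVector:
    """Normalized similarity weights w(i, j) for a single pixel i.

    Candidates j are the pixels of the search window around i that lie inside
    the image, enumerated in row-major order; the self term j = i is
    included. The returned weights sum to one.
    """
    img = validate_gray_image(image, levels).astype(np.float64)
    M, N = img.shape
    r, c = i
    if not (0 <= r < M and 0 <= c < N):
        raise ParameterError(f"pixel index {i} outside image of shape {img.shape}")

    pr = params.patch_radius
    padded = np.pad(img, pr, mode=params.pad_mode)
    sy, sx = _search_bounds(params, img.shape)

    def patch(py: int, px: int) -> np.ndarray:
        return padded[py : py + 2 * pr + 1, px : px + 2 * pr + 1]

    ref = patch(r, c)
    rows = range(max(0, r - sy), min(M, r + sy + 1))
    cols = range(max(0, c - sx), min(N, c + sx + 1))
    indices = np.array([(jr, jc) for jr in rows for jc in cols], dtype=np.int64)
    d2 = np.array([np.sum((ref - patch(jr, jc)) ** 2) for jr, jc in indices])
    raw = np.exp(-d2 / (params.h**2 * params.sigma**2))
    return WeightVector(weights=raw / raw.sum(), indices=indices)


def nlm_filter(
    image: np.ndarray,
    params: NLMParams = NLMParams(),
    levels: int = DEFAULT_LEVELS,
    quantize_output: bool = True,
) -> np.ndarray:
    """Non-local means filter of a gray-level image.

    Each output pixel is the weight-normalized average of the candidate
    pixels in its search window. With ``quantize_output`` (the default) the
    real-valued average is rounded half-up and clipped to [0, levels-1] so
    the result can index a gray-level histogram; pass ``False`` to obtain the
    pre-rounding float image.

    The computation loops over window offsets rather than pixels: for each
    offset the patchwise squared distances of every pixel to its shifted
    partner are obtained with one summed-area table, which reproduces the
    per-pixel definition exactly.
    """
    img = validate_gray_image(image, levels).astype(np.float64)
    M, N = img.shape
    pr = params.patch_radius
    side = 2 * pr + 1
    inv_bw = 1.0 / (params.h**2 * params.sigma**2)
    padded = np.pad(img, pr, mode=params.pad_mode)
    sy, sx = _search_bounds(params, img.shape)

    num = np.zeros((M, N))
    den = np.zeros((M, N))
    for dy in range(-sy, sy + 1):
        ay, by = max(0, -dy), M + 2 * pr - max(0, dy)
        if by - ay < side:
            continue
        for dx in range(-sx, sx + 1):
            ax, bx = max(0, -dx), N + 2 * pr - max(0, dx)
            if bx - ax < side:
                continue
            diff = padded[ay:by, ax:bx] - padded[ay + dy : by + dy, ax + dx : bx + dx]
            d2 = box_sum_valid(diff * diff, side)
            w = np.exp(-d2 * inv_bw)
            ys = slice(max(0, -dy), M - max(0, dy))
            xs = slice(max(0, -dx), N - max(0, dx))
            jys = slice(max(0, dy), M - max(0, -dy))
            jxs = slice(max(0, dx), N - max(0, -dx))
            num[ys, xs] += w * img[jys, jxs]
            den[ys, xs] += w
    out = num / den
    if quantize_output:
        return quantize(out, levels)
    return out
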