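"""Joint gray-level histograms of an image and a filtered companion.

The two-dimensional histogram of an image pair (I, J) is the L x L matrix

    p[i, j] = #{(x, y) : I(x, y) = i and J(x, y) = j} / (M N),

where J is a smoothed version of I. A threshold vector (s, t) splits the
matrix into four quadrants: the low-low box (i <= s, j <= t) and high-high
box (i > s, j > t) collect the background and object populations, while the
two off-diagonal quadrants collect edge and noise pixels whose original and
smoothed gray levels disagree.

When J is the non-local means filtered image the joint histogram is the
non-local-mean two-dimensional histogram (NLMTDH); with a local 3x3 mean it
is the classical Abutaleb-style histogram used by the 2-D baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._util import DEFAULT_LEVELS, box_sum_valid, quantize, validate_gray_image
from .exceptions import InputError, ParameterError

__all__ = [
    "Histogram2D",
    "build_joint_histogram",
    "build_1d_histogram",
    "local_mean_image",
    "quadrant_masses",
]


@dataclass(frozen=True)
class Histogram2D:
    """Joint probability matrix over (original, companion) gray-level pairs.

    Attributes
    ----------
    p
        (L, L) array; ``p[i, j]`` is the fraction of pixels with original
        level i and companion level j. Entries are nonnegative and sum to 1.
    n_pixels
        Number of pixels the histogram was counted from.
    """

    p: np.ndarray
    n_pixels: int

    @property
    def levels(self) -> int:
        return self.p.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write the probability matrix as L rows x L comma-separated columns."""
        np.savetxt(path, self.p, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, n_pixels: int = 0) -> "Histogram2D":
        p = np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
        return cls(p=p, n_pixels=n_pixels)


def build_joint_histogram(
    original: np.ndarray,
    companion: np.ndarray,
    levels: int = DEFAULT_LEVELS,
) -> Histogram2D:
    """Count the joint distribution of (original, companion) gray levels."""
    a = validate_gray_image(original, levels)
    b = validate_gray_image(companion, levels)
    if a.shape != b.shape:
        raise InputError(f"image shapes differ: {a.shape} vs {b.shape}")
    counts = np.bincount(a.ravel() * levels + b.ravel(), minlength=levels * levels)
    p = counts.reshape(levels, levels).astype(np.float64) / a.size
    return Histogram2D(p=p, n_pixels=int(a.size))


def build_1d_histogram(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Normalized length-L gray-level histogram of an image."""
    img = validate_gray_image(image, levels)
    return np.bincount(img.ravel(), minlength=levels).astype(np.float64) / img.size


def local_mean_image(
    image: np.ndarray, window: int = 3, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """Windowed local mean with reflect padding, rounded to integer levels.

    This is the smoothing stage of the classical two-dimensional histogram;
    a 3x3 window reproduces the usual local-mean companion image.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    img = validate_gray_image(image, levels).astype(np.float64)
    r = window // 2
    padded = np.pad(img, r, mode="reflect")
    means = box_sum_valid(padded, window) / float(window * window)
    return quantize(means, levels)


def quadrant_masses(
    h: Histogram2D, s: int, t: int
) -> tuple[float, float, float, float]:
    """Masses of the four quadrants induced by threshold vector (s, t).

    Returns (low-low, low-high, high-high, high-low):
    [0..s]x[0..t], [0..s]x[t+1..L-1], [s+1..L-1]x[t+1..L-1],
    [s+1..L-1]x[0..t]. The four masses sum to the total histogram mass.
    """
    L = h.levels
    if not (0 <= s <= L - 1 and 0 <= t <= L - 1):
        raise ParameterError(f"(s, t) = ({s}, {t}) outside [0, {L - 1}]^2")
    p = h.p
    r1 = float(p[: s + 1, : t + 1].sum())
    r2 = float(p[: s + 1, t + 1 :].sum())
    r3 = float(p[s + 1 :, t + 1 :].sum())
    r4 = float(p[s + 1 :, : t + 1].sum())
    return r1, r2, r3, r4
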