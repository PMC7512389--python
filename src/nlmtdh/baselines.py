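"""Classical thresholding baselines: Otsu, Kapur, minimum cross-entropy
(MCE), and the 2-D histogram minimum cross-entropy (2DMCE).

The three 1-D methods operate on the normalized gray-level histogram of the
image alone; a threshold s puts gray levels <= s in class 0. 2DMCE is the
ablation of the non-local means pipeline: the same relative-entropy
criterion minimized over the joint histogram of the image and its local
3x3 mean instead of its non-local means filtered companion.

All criteria share the conventions of the main method: natural logarithm,
zero-level and zero-probability terms contribute nothing, thresholds
leaving a class empty are skipped, and ties break toward the smallest
threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from ._util import DEFAULT_LEVELS, validate_gray_image
from .exceptions import DegenerateInputError, InputError
from .histogram2d import build_joint_histogram, local_mean_image
from .thresholding import ObjectiveValue, ThresholdVector, select_threshold

__all__ = [
    "otsu_threshold",
    "kapur_threshold",
    "mce_threshold",
    "mce2d_threshold",
    "threshold_mask",
]

_MASS_EPS = 1e-12


def _validate_hist(p: np.ndarray) -> np.ndarray:
    h = np.asarray(p, dtype=np.float64)
    if h.ndim != 1:
        raise InputError(f"histogram must be a vector, got shape {h.shape}")
    if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-6:
        raise InputError("histogram entries must be nonnegative and sum to 1")
    if np.count_nonzero(h > _MASS_EPS) < 2:
        raise DegenerateInputError(
            "histogram has fewer than two occupied gray levels; no threshold "
            "can separate two classes"
        )
    return h


def _best_feasible(score: np.ndarray, feasible: np.ndarray, maximize: bool) -> int:
    score = np.where(feasible, score, -np.inf if maximize else np.inf)
    return int(np.argmax(score) if maximize else np.argmin(score))


def otsu_threshold(p: np.ndarray) -> int:
    """Threshold maximizing the between-class variance P0 P1 (mu0 - mu1)^2."""
    h = _validate_hist(p)
    i = np.arange(h.size, dtype=np.float64)
    w = np.cumsum(h)           # P0(s)
    m = np.cumsum(i * h)       # first moment of class 0
    mt = m[-1]
    feasible = (w > _MASS_EPS) & (1.0 - w > _MASS_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = (mt * w - m) ** 2 / (w * (1.0 - w))
    return _best_feasible(var_b, feasible, maximize=True)


def kapur_threshold(p: np.ndarray) -> int:
    """Threshold maximizing the sum of Shannon entropies of the two
    normalized class distributions."""
    h = _validate_hist(p)
    w = np.cumsum(h)
    plogp = np.cumsum(xlogy(h, h))
    w1 = 1.0 - w
    feasible = (w > _MASS_EPS) & (w1 > _MASS_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = -plogp / w + np.log(w)
        h1 = -(plogp[-1] - plogp) / w1 + np.log(w1)
    return _best_feasible(h0 + h1, feasible, maximize=True)


def mce_threshold(p: np.ndarray) -> int:
    """Li-Lee minimum cross-entropy threshold.

    Minimizes -m0 log(mu0) - m1 log(mu1), where m_k is the first gray-level
    moment and mu_k the mean of class k (gray level 0 contributes nothing).
    """
    h = _validate_hist(p)
    i = np.arange(h.size, dtype=np.float64)
    w = np.cumsum(h)
    m = np.cumsum(i * h)
    w1 = 1.0 - w
    m1 = m[-1] - m
    feasible = (w > _MASS_EPS) & (w1 > _MASS_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        # m * log(mu) = m log m - m log P, safe at m == 0 via xlogy
        crit = -(xlogy(m, m) - xlogy(m, w)) - (xlogy(m1, m1) - xlogy(m1, w1))
    return _best_feasible(crit, feasible, maximize=False)


def mce2d_threshold(
    original: np.ndarray, window: int = 3, levels: int = DEFAULT_LEVELS
) -> tuple[ThresholdVector, ObjectiveValue]:
    """2-D minimum cross-entropy threshold vector.

    Builds the joint histogram of the image and its local-mean companion and
    minimizes the same relative-entropy objective as the main method; the
    only difference from the non-local means pipeline is the filter.
    """
    img = validate_gray_image(original, levels)
    companion = local_mean_image(img, window=window, levels=levels)
    return select_threshold(build_joint_histogram(img, companion, levels))


def threshold_mask(image: np.ndarray, s: int, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Binary mask from a scalar threshold: foreground where gray level > s."""
    return validate_gray_image(image, levels) > s
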