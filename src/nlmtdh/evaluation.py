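"""Segmentation evaluation: misclassification error against ground truth.

For two-class segmentation the misclassification error is

    ME = 1 - (|B_o ∩ B_T| + |F_o ∩ F_T|) / (|B_o| + |F_o|),

where B_o, F_o are the background and foreground pixel sets of the ground
truth and B_T, F_T those of the thresholded image. ME is 0 for a perfect
segmentation and 1 for a completely inverted one; the denominator is the
total pixel count, so ME equals the fraction of disagreeing pixels.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError

__all__ = ["misclassification_error", "polarity_align"]


def _validate_mask_pair(truth: np.ndarray, predicted: np.ndarray):
    a = np.asarray(truth)
    b = np.asarray(predicted)
    if a.ndim != 2 or b.ndim != 2:
        raise InputError("masks must be 2-D")
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def misclassification_error(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Fraction of pixels whose class label disagrees with ground truth."""
    a, b = _validate_mask_pair(truth, predicted)
    bg_match = int(np.count_nonzero(~a & ~b))
    fg_match = int(np.count_nonzero(a & b))
    return 1.0 - (bg_match + fg_match) / a.size


def polarity_align(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Return *predicted* or its complement, whichever has lower ME.

    A threshold method labels classes by gray level and cannot know which
    class the ground truth calls foreground; this resolves the ambiguity
    before scoring. Ties keep the original orientation.
    """
    a, b = _validate_mask_pair(truth, predicted)
    if misclassification_error(a, ~b) < misclassification_error(a, b):
        return ~b
    return b
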