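"""End-to-end segmentation pipeline: filter, joint histogram, threshold.

The main method chains three steps: (1) non-local means filtering of the
input image, (2) construction of the joint histogram of (original,
filtered) gray-level pairs, and (3) selection of the threshold vector
minimizing the relative-entropy objective, followed by binarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import DEFAULT_LEVELS
from .filtering import NLMParams, nlm_filter
from .histogram2d import Histogram2D, build_joint_histogram
from .thresholding import ObjectiveValue, ThresholdVector, binarize, select_threshold

__all__ = ["SegmentationResult", "segment"]


@dataclass(frozen=True)
class SegmentationResult:
    """Output of the full pipeline on one image."""

    mask: np.ndarray            # boolean foreground mask
    threshold: ThresholdVector  # selected (s, t)
    objective: ObjectiveValue   # D and class statistics at the optimum
    filtered: np.ndarray        # the non-local means companion image
    histogram: Histogram2D      # the joint histogram the search ran on


def segment(
    image: np.ndarray,
    params: NLMParams = NLMParams(),
    levels: int = DEFAULT_LEVELS,
) -> SegmentationResult:
    """Segment a gray-level image with the non-local means 2-D histogram
    minimum relative-entropy method."""
    filtered = nlm_filter(image, params, levels)
    hist = build_joint_histogram(image, filtered, levels)
    tv, obj = select_threshold(hist)
    mask = binarize(image, filtered, tv, levels)
    return SegmentationResult(
        mask=mask, threshold=tv, objective=obj, filtered=filtered, histogram=hist
    )
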