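"""Landmark-based intensity standardization.

Maps every scan onto a common intensity scale using a two-stage percentile
landmark method: a standard scale is learned as the per-percentile mean of
the per-image foreground percentiles, then each image is mapped by the
piecewise-linear transform taking its own foreground landmarks onto the
standard values.  Foreground is the union of the muscle masks, since the
downstream analysis only consumes within-muscle intensities.  Values beyond
the terminal landmarks follow the terminal linear segments (no clipping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: deciles plus the 1st and 99th percentiles
DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


class DegenerateImageError(ValueError):
    """The image has no usable intensity spread in its foreground."""


@dataclass
class StandardScale:
    """Learned common intensity scale: percentile positions and landmark values."""

    percentiles: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.percentiles) != len(self.values) or len(self.values) < 3:
            raise ValueError("percentiles and values must have equal length >= 3")
        if np.any(np.diff(self.percentiles) <= 0) or np.any(np.diff(self.values) <= 0):
            raise ValueError("percentiles and values must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"percentile": self.percentiles, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StandardScale":
        df = pd.read_csv(path)
        return cls(df["percentile"].to_numpy(), df["value"].to_numpy())


def _foreground_landmarks(
    image: np.ndarray, mask: np.ndarray, percentiles: Sequence[float]
) -> np.ndarray:
    fg = np.asarray(image)[np.asarray(mask, dtype=bool)]
    if fg.size == 0:
        raise DegenerateImageError("empty foreground mask")
    if fg.max() == fg.min():
        raise DegenerateImageError("constant-intensity foreground")
    return np.percentile(fg, percentiles)


def _spread_ties(values: np.ndarray, context: str) -> np.ndarray:
    """Make a non-decreasing landmark vector strictly increasing."""
    out = values.copy()
    eps = max(np.ptp(out), 1.0) * 1e-9
    bumped = False
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
            bumped = True
    if bumped:
        logger.warning("tied intensity landmarks spread by epsilon (%s)", context)
    return out


def learn_standard_scale(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> StandardScale:
    """Average the per-image foreground percentile landmarks into a common scale."""
    if len(images) < 2:
        raise ValueError("learning a standard scale requires at least 2 images")
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    stack = np.stack(
        [_foreground_landmarks(im, m, percentiles) for im, m in zip(images, masks)]
    )
    values = _spread_ties(stack.mean(axis=0), "standard scale")
    return StandardScale(np.asarray(percentiles, dtype=float), values)


def standardize_intensity(
    image: np.ndarray, mask: np.ndarray, scale: StandardScale
) -> np.ndarray:
    """Map an image onto the standard scale (applied to every pixel).

    The piecewise-linear map sends the image's own foreground landmarks onto
    ``scale.values``; it is monotone non-decreasing, and the foreground
    median lands exactly on the standard median landmark (50 is a landmark
    percentile by default).
    """
    landmarks = _spread_ties(
        _foreground_landmarks(image, mask, scale.percentiles), "image landmarks"
    )
    img = np.asarray(image, dtype=float)
    out = np.interp(img, landmarks, scale.values)
    # extend the terminal segments instead of clipping
    lo_slope = (scale.values[1] - scale.values[0]) / (landmarks[1] - landmarks[0])
    hi_slope = (scale.values[-1] - scale.values[-2]) / (
        landmarks[-1] - landmarks[-2]
    )
    below = img < landmarks[0]
    above = img > landmarks[-1]
    out[below] = scale.values[0] + (img[below] - landmarks[0]) * lo_slope
    out[above] = scale.values[-1] + (img[above] - landmarks[-1]) * hi_slope
    return out
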