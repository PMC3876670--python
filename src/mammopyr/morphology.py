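"""Flat grayscale morphology and the top-hat/bottom-hat enhancement.

All operators use a flat rectangular structuring element with odd dimensions
(unambiguous center) and symmetric border reflection.  For a flat SE the
erosion/dilation reduce to sliding-window minimum/maximum.  The enhancement
combination

    C = I + TH - BH = 3*I - opening(I) - closing(I)

lifts bright details smaller than the SE (top-hat) and suppresses dark ones
(bottom-hat); applied here to the coarse low-pass pyramid residual.  Results
are kept as unclipped floats — C can leave the nominal intensity range and is
only clipped at the very end of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .errors import ParameterError
from .pyramid import as_image

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "opening",
    "closing",
    "top_hat",
    "bottom_hat",
    "morph_enhance",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat rectangular neighborhood with odd dimensions and centered origin."""

    shape: tuple[int, int] = (15, 15)

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ParameterError(f"structuring element must be non-empty, got {self.shape}")
        if h % 2 == 0 or w % 2 == 0:
            raise ParameterError(
                f"structuring element dimensions must be odd, got {self.shape}"
            )

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        return cls((size, size))


def _check(image, se: StructuringElement) -> np.ndarray:
    arr = as_image(image)
    if se.shape[0] > arr.shape[0] or se.shape[1] > arr.shape[1]:
        raise ParameterError(
            f"structuring element {se.shape} larger than image {arr.shape}"
        )
    return arr


def erode(image, se: StructuringElement) -> np.ndarray:
    """Sliding-window minimum over the SE window, reflective borders."""
    arr = _check(image, se)
    return minimum_filter(arr, size=se.shape, mode="reflect")


def dilate(image, se: StructuringElement) -> np.ndarray:
    """Sliding-window maximum over the SE window, reflective borders."""
    arr = _check(image, se)
    return maximum_filter(arr, size=se.shape, mode="reflect")


def opening(image, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation; removes bright details smaller than the SE."""
    return dilate(erode(image, se), se)


def closing(image, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion; fills dark details smaller than the SE."""
    return erode(dilate(image, se), se)


def top_hat(image, se: StructuringElement) -> np.ndarray:
    """I - opening(I): bright details smaller than the SE; >= 0 everywhere."""
    arr = _check(image, se)
    return arr - opening(arr, se)


def bottom_hat(image, se: StructuringElement) -> np.ndarray:
    """closing(I) - I: dark details smaller than the SE; >= 0 everywhere."""
    arr = _check(image, se)
    return closing(arr, se) - arr


def morph_enhance(image, se: StructuringElement) -> np.ndarray:
    """C = I + top_hat(I) - bottom_hat(I), computed unclipped in float."""
    arr = _check(image, se)
    return arr + top_hat(arr, se) - bottom_hat(arr, se)
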