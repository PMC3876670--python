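"""Quantitative image-quality metrics: contrast criterion, CII, SNR.

Three measures of enhancement quality:

* ``contrast_criterion`` (Cc): the population variance of the intensities,
  mean(f'^2) - mean(f')^2.  Larger means more global contrast; 0 for a
  constant image; shift-invariant and quadratic under scaling.
* ``cii``: contrast improvement index, the ratio of mean local region
  contrast of the processed image to that of the original, where local
  contrast at each pixel is (Xmax - Xmin)/(Xmax + Xmin) over an odd window
  (default 5x5).  CII of an image against itself is exactly 1.
* ``snr_db``: reference-based signal-to-noise ratio,
  10*log10(sum(ref^2) / sum((enh - ref)^2)) in decibels; identical images
  yield +inf (signaled, not raised).

``region_contrast`` implements the two-region form (m_f - m_b)/(m_f + m_b)
for explicit foreground/background masks (used with phantom ground truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .errors import (
    DegenerateInputError,
    ParameterError,
    ShapeError,
    UndefinedMetricError,
)
from .pyramid import as_image

__all__ = [
    "MetricsReport",
    "contrast_criterion",
    "local_contrast",
    "mean_region_contrast",
    "cii",
    "snr_db",
    "region_contrast",
    "report",
]


def contrast_criterion(image) -> float:
    """Population variance of intensities, mean(f'^2) - mean(f')^2.

    Evaluated two-pass (mean of squared deviations) in double precision, so a
    constant image yields exactly 0.
    """
    arr = as_image(image)
    if arr.size == 0:
        raise DegenerateInputError("empty image has no contrast")
    if np.ptp(arr) == 0.0:
        return 0.0  # exact, avoids summation-rounding residue
    m = float(arr.mean())
    return float(np.mean((arr - m) ** 2))


def local_contrast(image, window: int = 5) -> np.ndarray:
    """Per-pixel (max - min)/(max + min) over an odd sliding window.

    Reflective borders; windows whose max + min is zero contribute 0 (only
    all-zero neighborhoods for non-negative images).  Values lie in [0, 1]
    for non-negative images.
    """
    arr = as_image(image)
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    mx = maximum_filter(arr, size=window, mode="reflect")
    mn = minimum_filter(arr, size=window, mode="reflect")
    denom = mx + mn
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0.0, (mx - mn) / denom, 0.0)
    return out


def mean_region_contrast(image, window: int = 5) -> float:
    """Image-average local contrast: the operative C of the CII ratio."""
    return float(local_contrast(image, window).mean())


def cii(processed, original, window: int = 5) -> float:
    """Contrast improvement index C_processed / C_original.

    Raises UndefinedMetricError when the original has zero mean local
    contrast (e.g. a constant image).
    """
    p = as_image(processed)
    o = as_image(original)
    if p.shape != o.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {o.shape}")
    c_orig = mean_region_contrast(o, window)
    if c_orig == 0.0:
        raise UndefinedMetricError("original image has zero local contrast")
    return mean_region_contrast(p, window) / c_orig


def snr_db(enhanced, reference) -> float:
    """10*log10(sum(ref^2) / sum((enh - ref)^2)); +inf for identical inputs."""
    e = as_image(enhanced)
    r = as_image(reference)
    if e.shape != r.shape:
        raise ShapeError(f"shape mismatch: {e.shape} vs {r.shape}")
    noise = float(((e - r) ** 2).sum())
    if noise == 0.0:
        return math.inf
    signal = float((r * r).sum())
    if signal == 0.0:
        return -math.inf
    return 10.0 * math.log10(signal / noise)


def region_contrast(image, foreground_mask, background_mask) -> float:
    """(m_f - m_b)/(m_f + m_b) for explicit foreground/background masks."""
    arr = as_image(image)
    fg = np.asarray(foreground_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if fg.shape != arr.shape or bg.shape != arr.shape:
        raise ShapeError("mask shapes must match the image")
    if not fg.any() or not bg.any():
        raise DegenerateInputError("foreground and background masks must be non-empty")
    m_f = float(arr[fg].mean())
    m_b = float(arr[bg].mean())
    if m_f + m_b == 0.0:
        raise UndefinedMetricError("m_f + m_b is zero")
    return (m_f - m_b) / (m_f + m_b)


CSV_HEADER = "method,contrast,cii,snr"


@dataclass
class MetricsReport:
    """Bundle of the three metrics for one processed/original pair."""

    contrast_cc: float
    cii: float
    snr_db: float
    window: int = 5
    method: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "contrast": self.contrast_cc,
            "cii": self.cii,
            "snr": None if math.isinf(self.snr_db) else self.snr_db,
            "snr_infinite": math.isinf(self.snr_db),
            "window": self.window,
        }
        d.update(self.extras)
        return d

    def to_csv_row(self) -> str:
        snr = "inf" if math.isinf(self.snr_db) else f"{self.snr_db:.4f}"
        return f"{self.method},{self.contrast_cc:.6f},{self.cii:.6f},{snr}"


def report(processed, original, window: int = 5, method: str = "") -> MetricsReport:
    """Compute Cc, CII and SNR of `processed` against `original`."""
    return MetricsReport(
        contrast_cc=contrast_criterion(processed),
        cii=cii(processed, original, window),
        snr_db=snr_db(processed, original),
        window=window,
        method=method,
    )
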