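"""Synthetic mammography-like phantom with ground truth.

Emulates the statistical structure of a digital mammogram so the enhancement
pipeline can be exercised and measured without clinical data:

* a half-elliptical breast support (chest wall at the left edge) over a dark
  background, with a smooth intensity fall-off toward the skin line;
* band-limited fibroglandular texture (Gaussian-filtered white noise);
* low-contrast soft-edged discs standing in for masses (a few percent
  relative contrast);
* bright punctate microcalcifications, 1-3 px across;
* additive Gaussian noise, applied last; values clipped to [0, 1].

Everything is driven by numpy's PCG64 Generator through an explicit seed, so
identical specs produce bit-identical phantoms across platforms.  The truth
object carries the breast support, a mass mask, and calcification coordinates
for mask-based contrast measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from scipy.special import expit

from .errors import DegenerateInputError, ParameterError
from .metrics import region_contrast
from .pyramid import as_image

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "measure_target_contrast"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom realization."""

    shape: tuple[int, int] = (256, 512)
    background_level: float = 0.35
    exterior_level: float = 0.08  # darkfield offset, kept well above noise_sigma
    gradient_amplitude: float = 0.10
    texture_sigma: float = 4.0
    texture_strength: float = 0.03
    # explicit (row, col, radius, contrast_delta) tuples, or random placement
    masses: tuple | None = None
    n_masses: int = 3
    mass_radius: tuple[float, float] = (10.0, 18.0)
    mass_contrast: float = 0.05
    # explicit (row, col, amplitude) tuples, or random placement
    calcifications: tuple | None = None
    n_calcifications: int = 12
    calc_amplitude: float = 0.25
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 32 or w < 32:
            raise ParameterError(f"phantom shape must be at least 32x32, got {self.shape}")
        if not (0.0 < self.background_level < 1.0):
            raise ParameterError("background_level must lie in (0, 1)")
        if not (0.0 <= self.exterior_level < self.background_level):
            raise ParameterError("exterior_level must lie in [0, background_level)")
        if self.noise_sigma < 0 or self.texture_strength < 0:
            raise ParameterError("noise_sigma and texture_strength must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth masks and object coordinates for a generated phantom."""

    breast_mask: np.ndarray
    mass_mask: np.ndarray
    calc_coordinates: list = field(default_factory=list)


def _breast_support(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Half-ellipse support anchored at the left edge; returns (mask, radial)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    a = 0.46 * h  # vertical semi-axis
    b = 0.92 * w  # horizontal semi-axis
    radial = np.sqrt(((yy - h / 2.0) / a) ** 2 + (xx / b) ** 2)
    return radial <= 1.0, radial


def generate(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the phantom described by `spec`; reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    mask, radial = _breast_support(spec.shape)
    soft = gaussian_filter(mask.astype(np.float64), 3.0, mode="reflect")

    # smooth background: brighter near the chest wall, falling toward the edge
    bg = spec.background_level * (1.0 - spec.gradient_amplitude * np.clip(radial, 0, 1))
    img = spec.exterior_level + (bg - spec.exterior_level) * soft

    if spec.texture_strength > 0:
        tex = gaussian_filter(rng.standard_normal((h, w)), spec.texture_sigma,
                              mode="reflect")
        std = tex.std()
        if std > 0:
            img = img + spec.texture_strength * (tex / std) * soft

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    interior = binary_erosion(mask, iterations=4)

    # masses: soft-edged low-contrast discs
    mass_mask = np.zeros(spec.shape, dtype=bool)
    if spec.masses is not None:
        masses = [tuple(m) for m in spec.masses]
        for cy, cx, r, _ in masses:
            if not (0 <= int(cy) < h and 0 <= int(cx) < w) or not mask[int(cy), int(cx)]:
                raise ParameterError(f"mass at ({cy}, {cx}) lies outside the breast support")
    else:
        masses = []
        for _ in range(spec.n_masses):
            r = float(rng.uniform(*spec.mass_radius))
            cy, cx = _sample_inside(rng, interior, margin=int(np.ceil(r)) + 4)
            masses.append((cy, cx, r, spec.mass_contrast))
    for cy, cx, r, delta in masses:
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img = img + delta * expit((r - dist) / 1.0)
        mass_mask |= dist <= r

    # microcalcifications: punctate 3x3 stamps with a bright center
    calc_coords: list[tuple[int, int]] = []
    stamp = np.outer([0.3, 1.0, 0.3], [0.3, 1.0, 0.3])
    if spec.calcifications is not None:
        calcs = [tuple(c) for c in spec.calcifications]
        for cy, cx, _ in calcs:
            if not (1 <= int(cy) < h - 1 and 1 <= int(cx) < w - 1) or not mask[int(cy), int(cx)]:
                raise ParameterError(f"calcification at ({cy}, {cx}) lies outside the support")
    else:
        calcs = []
        for _ in range(spec.n_calcifications):
            cy, cx = _sample_inside(rng, interior, margin=2)
            calcs.append((cy, cx, spec.calc_amplitude))
    for cy, cx, amp in calcs:
        cy, cx = int(cy), int(cx)
        img[cy - 1:cy + 2, cx - 1:cx + 2] += amp * stamp
        calc_coords.append((cy, cx))

    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal((h, w))

    img = np.clip(img, 0.0, 1.0)
    truth = PhantomTruth(breast_mask=mask, mass_mask=mass_mask,
                         calc_coordinates=calc_coords)
    return img, truth


def _sample_inside(rng: np.random.Generator, mask: np.ndarray, margin: int) -> tuple[int, int]:
    """Draw a pixel uniformly from the mask eroded by `margin` pixels."""
    safe = binary_erosion(mask, iterations=max(margin, 1))
    idx = np.flatnonzero(safe)
    if idx.size == 0:
        raise ParameterError("phantom too small to place objects with the given margin")
    flat = int(rng.integers(0, idx.size))
    return tuple(np.unravel_index(idx[flat], mask.shape))  # type: ignore[return-value]


def measure_target_contrast(image, truth: PhantomTruth) -> float:
    """Mass-vs-annulus contrast (m_f - m_b)/(m_f + m_b) using truth masks.

    Foreground is the mass mask; background is a surrounding annulus inside
    the breast support, separated from the mass edge by a two-pixel guard.
    """
    arr = as_image(image)
    if not truth.mass_mask.any():
        raise DegenerateInputError("phantom truth contains no masses")
    inner = binary_dilation(truth.mass_mask, iterations=2)
    outer = binary_dilation(truth.mass_mask, iterations=8)
    annulus = outer & ~inner & truth.breast_mask
    return region_contrast(arr, truth.mass_mask, annulus)
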