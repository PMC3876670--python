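"""Histogram-equalization family: HE, AHE and contrast-limited AHE.

Plain histogram equalization remaps gray level r_k through the cumulative
distribution, s_k = (L-1) * sum_{j<=k} p_r(r_j), which flattens the global
histogram.  Adaptive HE applies the same remapping per tile; contrast-limited
AHE (CLAHE) additionally clips each tile histogram at a ceiling of
clip_limit * n / L counts and redistributes the clipped excess uniformly over
all bins before building the tile mapping, which bounds the slope of the
transfer function and hence the local noise amplification.  Per-pixel output
is the bilinear blend of the four surrounding tile mappings (clamped to the
nearest tile at the borders), the standard interpolated-CLAHE scheme.

Float images are binned uniformly over their declared value range into L
half-open bins (the last bin closed).  Signed pyramid detail bands are
handled by `equalize_band`: affine-map the band to [0, 1] by its own span,
run CLAHE, optionally Gaussian-smooth to restrain amplified noise, and map
back to the original span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError, ParameterError
from .pyramid import as_image

__all__ = [
    "GrayHistogram",
    "TransferFunction",
    "ClaheParams",
    "compute_histogram",
    "equalization_map",
    "clip_histogram",
    "apply_he",
    "apply_clahe",
    "equalize_band",
]


@dataclass(frozen=True)
class GrayHistogram:
    """Occurrence counts per gray level (float counts after clipping)."""

    counts: np.ndarray
    n: float
    L: int

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.float64) / self.n


@dataclass(frozen=True)
class TransferFunction:
    """Monotone gray-level remapping s_k in [0, L-1]."""

    mapping: np.ndarray
    L: int


@dataclass(frozen=True)
class ClaheParams:
    """Tile grid, clip limit (multiple of the uniform bin height), bin count."""

    tiles: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0
    n_bins: int = 256
    redistribute: bool = True

    def __post_init__(self) -> None:
        r, c = self.tiles
        if r < 1 or c < 1:
            raise ParameterError(f"tiles must be positive, got {self.tiles}")
        if self.clip_limit < 1.0:
            raise ParameterError(
                f"clip_limit must be >= 1 (1 = maximal limiting), got {self.clip_limit}"
            )
        if self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")


def _quantize(arr: np.ndarray, L: int, value_range: tuple[float, float]) -> np.ndarray:
    lo, hi = value_range
    if not hi > lo:
        raise ParameterError(f"value_range must be increasing, got {value_range}")
    idx = np.floor((arr - lo) / (hi - lo) * L).astype(np.intp)
    return np.clip(idx, 0, L - 1)


def compute_histogram(image, L: int, value_range: tuple[float, float] = (0.0, 1.0)) -> GrayHistogram:
    """Tally pixels into L uniform bins over the declared value range."""
    arr = as_image(image)
    if L < 2:
        raise ParameterError(f"L must be >= 2, got {L}")
    bins = _quantize(arr, L, value_range)
    counts = np.bincount(bins.ravel(), minlength=L).astype(np.float64)
    return GrayHistogram(counts=counts, n=float(arr.size), L=L)


def equalization_map(hist: GrayHistogram) -> TransferFunction:
    """s_k = (L-1) * cumulative probability up to level k."""
    if hist.n <= 0:
        raise DegenerateInputError("cannot equalize an empty histogram (n = 0)")
    mapping = (hist.L - 1) * np.cumsum(hist.probabilities)
    return TransferFunction(mapping=mapping, L=hist.L)


def clip_histogram(hist: GrayHistogram, clip_limit: float, max_iter: int = 5) -> GrayHistogram:
    """Clip bins at clip_limit * n / L and spread the excess uniformly.

    Redistribution can push bins back over the ceiling, so clip-and-spread is
    iterated until the residual excess is below one count or max_iter passes
    have run.  The total count is conserved exactly.
    """
    if clip_limit < 1.0:
        raise ParameterError(f"clip_limit must be >= 1, got {clip_limit}")
    counts = np.asarray(hist.counts, dtype=np.float64).copy()
    ceiling = clip_limit * hist.n / hist.L
    for _ in range(max_iter):
        excess = float(np.clip(counts - ceiling, 0.0, None).sum())
        if excess < 1.0:
            break
        counts = np.minimum(counts, ceiling) + excess / hist.L
    return GrayHistogram(counts=counts, n=hist.n, L=hist.L)


def _tile_mapping(tile: np.ndarray, params: ClaheParams,
                  value_range: tuple[float, float]) -> np.ndarray:
    hist = compute_histogram(tile, params.n_bins, value_range)
    if params.redistribute:
        hist = clip_histogram(hist, params.clip_limit)
    else:
        counts = np.minimum(hist.counts, params.clip_limit * hist.n / hist.L)
        hist = GrayHistogram(counts=counts, n=float(counts.sum()), L=hist.L)
    return equalization_map(hist).mapping


def apply_he(image, L: int = 256, value_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Global histogram equalization; output rescaled back to value_range."""
    arr = as_image(image)
    tf = equalization_map(compute_histogram(arr, L, value_range))
    bins = _quantize(arr, L, value_range)
    lo, hi = value_range
    return lo + tf.mapping[bins] / (L - 1) * (hi - lo)


def _tile_axis(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Tile edges and centers along one axis of length n split into k tiles."""
    edges = np.round(np.linspace(0, n, k + 1)).astype(int)
    if np.any(np.diff(edges) < 2):
        raise ParameterError(
            f"tile grid of {k} does not fit axis of length {n}: each tile needs >= 2 pixels"
        )
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    return edges, centers


def apply_clahe(image, params: ClaheParams,
                value_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization with tile interpolation.

    With a 1x1 tile grid and an effectively infinite clip limit this reduces
    pixelwise to plain `apply_he` (the degeneracy ladder CLAHE -> AHE -> HE).
    """
    arr = as_image(image)
    rows, cols = params.tiles
    h, w = arr.shape
    r_edges, r_centers = _tile_axis(h, rows)
    c_edges, c_centers = _tile_axis(w, cols)

    L = params.n_bins
    mappings = np.empty((rows, cols, L), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = arr[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            mappings[i, j] = _tile_mapping(tile, params, value_range)

    # fractional tile coordinate of every pixel, clamped at the outer centers
    pos_r = np.interp(np.arange(h), r_centers, np.arange(rows, dtype=np.float64))
    pos_c = np.interp(np.arange(w), c_centers, np.arange(cols, dtype=np.float64))
    r0 = np.floor(pos_r).astype(np.intp)
    c0 = np.floor(pos_c).astype(np.intp)
    wr = (pos_r - r0)[:, None]
    wc = (pos_c - c0)[None, :]
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)

    bins = _quantize(arr, L, value_range)
    r0 = r0[:, None]
    r1 = r1[:, None]
    c0 = c0[None, :]
    c1 = c1[None, :]
    s = (
        (1 - wr) * (1 - wc) * mappings[r0, c0, bins]
        + (1 - wr) * wc * mappings[r0, c1, bins]
        + wr * (1 - wc) * mappings[r1, c0, bins]
        + wr * wc * mappings[r1, c1, bins]
    )
    lo, hi = value_range
    return lo + s / (L - 1) * (hi - lo)


def equalize_band(band, params: ClaheParams, smooth_sigma: float = 0.5) -> np.ndarray:
    """CLAHE on a signed pyramid detail band, with optional noise-restraining blur.

    The band is affinely mapped onto [0, 1] by its own min/max, equalized,
    Gaussian-smoothed with smooth_sigma (0 disables), and mapped back to its
    original span.  A zero-span (constant) band passes through unchanged.
    """
    arr = as_image(band)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo == 0.0:
        return arr.copy()
    norm = (arr - lo) / (hi - lo)
    eq = apply_clahe(norm, params, value_range=(0.0, 1.0))
    if smooth_sigma > 0:
        eq = gaussian_filter(eq, smooth_sigma, mode="reflect")
    return eq * (hi - lo) + lo
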