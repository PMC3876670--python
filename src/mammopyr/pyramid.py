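"""Gaussian/Laplacian image pyramid with exact reconstruction.

An image is repeatedly low-pass filtered with a separable 5-tap generating
kernel and decimated by two, producing the Gaussian chain g_0 (the input),
g_1, ..., g_L.  Each detail band is the difference between one Gaussian level
and the expansion of the next coarser one,

    b_k = g_k - EXPAND(g_{k+1}),   k = 0 ... L-1,

so that the pyramid (b_0, ..., b_{L-1}, g_L) is exactly invertible by the
reverse recursion g_k = EXPAND(g_{k+1}) + b_k, regardless of the kernel used,
as long as decomposition and reconstruction use the same EXPAND.

The generating kernel is the classic one-parameter 5-tap family
w = [1/4 - a/2, 1/4, a, 1/4, 1/4 - a/2]; a = 0.4 gives the closest-to-Gaussian
member and is the default throughout the package.  Borders are handled by
symmetric (edge-repeating) reflection so constant images stay constant.
Odd dimensions are supported: reduction takes every other sample starting at
index 0 (output size ceil(n/2)); expansion targets an explicit shape, which
must be 2n or 2n-1 per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .errors import (
    DecompositionDepthError,
    ParameterError,
    PyramidIntegrityError,
    ShapeError,
)

__all__ = [
    "GenerationKernel",
    "LaplacianPyramid",
    "make_kernel",
    "reduce",
    "expand",
    "decompose",
    "reconstruct",
]


def as_image(values) -> np.ndarray:
    """Validate and return a 2-D float64 image array.

    Raises ParameterError on non-2-D input or non-finite values.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ParameterError(f"image dimensions must be >= 1, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("image contains NaN or Inf values")
    return arr


@dataclass(frozen=True)
class GenerationKernel:
    """Symmetric, unit-sum 5-tap low-pass generating kernel."""

    taps: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.taps) != 5:
            raise ParameterError("generating kernel must have exactly 5 taps")
        t = np.asarray(self.taps, dtype=np.float64)
        if not (np.isclose(t[0], t[4]) and np.isclose(t[1], t[3])):
            raise ParameterError("generating kernel must be symmetric")
        if not np.isclose(t.sum(), 1.0):
            raise ParameterError("generating kernel taps must sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.taps, dtype=np.float64)


def make_kernel(a_param: float = 0.4) -> GenerationKernel:
    """Build the parametric generating kernel [1/4-a/2, 1/4, a, 1/4, 1/4-a/2]."""
    if not (0.0 < a_param < 1.0):
        raise ParameterError(f"a_param must lie in (0, 1), got {a_param}")
    edge = 0.25 - a_param / 2.0
    return GenerationKernel((edge, 0.25, a_param, 0.25, edge))


def reduce(image, kernel: GenerationKernel | None = None) -> np.ndarray:
    """Low-pass filter with the separable 5-tap kernel and decimate by 2.

    Output dimensions are ceil(dim/2) per axis (samples at even indices are
    kept).  Symmetric border reflection, so constants are preserved exactly.
    """
    arr = as_image(image)
    if min(arr.shape) < 2:
        raise DecompositionDepthError(
            f"cannot reduce an image of shape {arr.shape}: both dims must be >= 2"
        )
    k = (kernel or make_kernel()).array
    sm = correlate1d(arr, k, axis=0, mode="reflect")
    sm = correlate1d(sm, k, axis=1, mode="reflect")
    return sm[::2, ::2]


def _expand_axis(arr: np.ndarray, taps: np.ndarray, target: int, axis: int) -> np.ndarray:
    """Upsample one axis from n to target in {2n-1, 2n} samples.

    Equivalent to zero-insertion followed by convolution with the doubled
    kernel, with out-of-range source indices reflected symmetrically.  The
    even/odd output phases each see weights summing to one, so constants
    expand to the same constant.
    """
    n = arr.shape[axis]
    if target not in (2 * n, 2 * n - 1):
        raise ShapeError(
            f"target size {target} incompatible with source size {n} "
            f"(must be {2 * n - 1} or {2 * n})"
        )
    a = np.moveaxis(arr, axis, 0)
    pad = [(1, 1)] + [(0, 0)] * (a.ndim - 1)
    ap = np.pad(a, pad, mode="symmetric")  # ap[i+1] == a[i]
    out = np.empty((target,) + a.shape[1:], dtype=np.float64)
    n_even = (target + 1) // 2
    n_odd = target // 2
    # even outputs sit on source samples: w2*x[k] + w0*(x[k-1] + x[k+1])
    out[0::2] = 2.0 * (
        taps[2] * ap[1 : 1 + n_even] + taps[0] * (ap[0:n_even] + ap[2 : 2 + n_even])
    )
    # odd outputs sit between samples: w1*(x[k] + x[k+1])
    out[1::2] = 2.0 * taps[1] * (ap[1 : 1 + n_odd] + ap[2 : 2 + n_odd])
    return np.moveaxis(out, 0, axis)


def expand(image, kernel: GenerationKernel | None = None, target_shape=None) -> np.ndarray:
    """Upsample an image to target_shape (each dim 2n or 2n-1 of the source)."""
    arr = as_image(image)
    if target_shape is None:
        target_shape = (2 * arr.shape[0], 2 * arr.shape[1])
    taps = (kernel or make_kernel()).array
    out = _expand_axis(arr, taps, int(target_shape[0]), axis=0)
    out = _expand_axis(out, taps, int(target_shape[1]), axis=1)
    return out


def _ceil_half(shape: tuple[int, int]) -> tuple[int, int]:
    return ((shape[0] + 1) // 2, (shape[1] + 1) // 2)


@dataclass
class LaplacianPyramid:
    """Ordered signed detail bands b_0...b_{L-1} plus the low-pass residual g_L."""

    bands: list[np.ndarray]
    residual: np.ndarray
    original_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.original_shape is None:
            self.original_shape = tuple(self.bands[0].shape) if self.bands else tuple(
                self.residual.shape
            )

    @property
    def levels(self) -> int:
        return len(self.bands)

    def validate(self) -> None:
        """Check the shape chain; raise PyramidIntegrityError if broken."""
        if self.levels < 1:
            raise PyramidIntegrityError("pyramid must contain at least one band")
        if tuple(self.bands[0].shape) != tuple(self.original_shape):
            raise PyramidIntegrityError(
                f"band 0 shape {self.bands[0].shape} != original {self.original_shape}"
            )
        shape = tuple(self.bands[0].shape)
        for k in range(1, self.levels):
            shape = _ceil_half(shape)
            if tuple(self.bands[k].shape) != shape:
                raise PyramidIntegrityError(
                    f"band {k} shape {self.bands[k].shape} != expected {shape}"
                )
        if tuple(self.residual.shape) != _ceil_half(shape):
            raise PyramidIntegrityError(
                f"residual shape {self.residual.shape} != expected {_ceil_half(shape)}"
            )


def decompose(image, levels: int, kernel: GenerationKernel | None = None) -> LaplacianPyramid:
    """Decompose an image into `levels` detail bands plus a low-pass residual."""
    arr = as_image(image)
    if levels < 1:
        raise ParameterError(f"levels must be >= 1, got {levels}")
    kernel = kernel or make_kernel()
    gs = [arr]
    for _ in range(levels):
        if min(gs[-1].shape) < 2:
            raise DecompositionDepthError(
                f"levels={levels} too deep for image shape {arr.shape}"
            )
        gs.append(reduce(gs[-1], kernel))
    bands = [gs[k] - expand(gs[k + 1], kernel, gs[k].shape) for k in range(levels)]
    return LaplacianPyramid(bands=bands, residual=gs[-1], original_shape=tuple(arr.shape))


def reconstruct(pyr: LaplacianPyramid, kernel: GenerationKernel | None = None) -> np.ndarray:
    """Invert decompose(): g_k = EXPAND(g_{k+1}) + b_k down to full resolution.

    With unmodified bands this reproduces the original image to floating-point
    precision (the transform is exactly invertible by construction).
    """
    pyr.validate()
    kernel = kernel or make_kernel()
    g = np.asarray(pyr.residual, dtype=np.float64)
    for band in reversed(pyr.bands):
        g = expand(g, kernel, band.shape) + band
    return g
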