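"""Global nonlinear gain adjustment of the reconstructed image.

The gain curve is a difference of two logistic sigmoids,

    f(z) = a * [sigm(c*(z - b)) - sigm(-c*(z + b))],
    a    = 1 / (sigm(c*(1 - b)) - sigm(-c*(1 + b))),

an odd, strictly increasing S-curve on [-1, 1] with fixed points f(0) = 0 and
f(+-1) = +-1.  b in (0, 1) positions the steep region (contrast is expanded
around intensities near +-b) and c > 0 sets its slope.  The fixed points at
+-1 dictate the working domain: an image is affinely mapped from its own
[min, max] span onto [-1, 1], remapped through f, and mapped back, so a
constant image passes through unchanged and the span endpoints are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ParameterError
from .pyramid import as_image

__all__ = ["GainParams", "sigm", "gain_normalizer", "gain_curve", "gain_slope", "apply_gain"]


def sigm(z):
    """Logistic sigmoid 1 / (1 + exp(-z))."""
    return expit(z)


def gain_normalizer(b: float, c: float) -> float:
    """Normalizer a making f(1) = 1; requires 0 < b < 1 and c > 0."""
    if not (0.0 < b < 1.0):
        raise ParameterError(f"b must lie in (0, 1), got {b}")
    if not c > 0.0:
        raise ParameterError(f"c must be > 0, got {c}")
    return float(1.0 / (sigm(c * (1.0 - b)) - sigm(-c * (1.0 + b))))


@dataclass(frozen=True)
class GainParams:
    """Enhancement-ratio coefficient b in (0,1) and slope coefficient c > 0."""

    b: float = 0.35
    c: float = 20.0

    def __post_init__(self) -> None:
        gain_normalizer(self.b, self.c)  # validates

    @property
    def a(self) -> float:
        """Derived normalizer, always recomputed from b and c."""
        return gain_normalizer(self.b, self.c)


def gain_curve(z, params: GainParams):
    """Evaluate f(z) = a*[sigm(c(z-b)) - sigm(-c(z+b))] elementwise."""
    z = np.asarray(z, dtype=np.float64)
    b, c = params.b, params.c
    return params.a * (sigm(c * (z - b)) - sigm(-c * (z + b)))


def gain_slope(z, params: GainParams):
    """Analytic derivative f'(z) = a*c*[sigm'(c(z-b)) + sigm'(-c(z+b))].

    Evaluated as sigm'(x) = sigm(x)*sigm(-x), which keeps the derivative
    strictly positive in floating point even where the sampled curve itself
    saturates at +-1 (large c): f is strictly increasing everywhere.
    """
    z = np.asarray(z, dtype=np.float64)
    b, c = params.b, params.c
    u = c * (z - b)
    v = -c * (z + b)
    return params.a * c * (sigm(u) * sigm(-u) + sigm(v) * sigm(-v))


def apply_gain(image, params: GainParams) -> np.ndarray:
    """Remap an image through the gain curve on its own [min, max] span.

    The span is mapped to [-1, 1], f applied pointwise, and the result mapped
    back; constant images pass through unchanged.
    """
    arr = as_image(image)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo == 0.0:
        return arr.copy()
    z = 2.0 * (arr - lo) / (hi - lo) - 1.0
    f = gain_curve(z, params)
    return (f + 1.0) / 2.0 * (hi - lo) + lo
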