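"""End-to-end multiscale enhancement pipeline.

Stage order is fixed:

1. Laplacian pyramid decomposition (`levels` detail bands + low-pass residual);
2. CLAHE on every detail band (each band normalized to [0,1] by its own span,
   equalized, Gaussian-smoothed to restrain amplified noise, mapped back);
3. top-hat/bottom-hat morphological enhancement C = I + TH - BH of the
   low-pass residual (optionally also of the coarsest `morph_levels` detail
   bands);
4. pyramid reconstruction;
5. global sigmoid-difference gain remapping, strictly last.

Intermediate arrays are unclipped floats; clipping to the declared output
range happens only when writing a file.  Each stage preserves the image shape
and each stage can be bypassed, in which case the pipeline reduces exactly to
the remaining composition (with all three bypassed it is a pure
decompose/reconstruct round trip, identity to float precision).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .clahe import ClaheParams, equalize_band
from .errors import ConfigError, ParameterError
from .gain import GainParams, apply_gain
from .morphology import StructuringElement, morph_enhance
from .metrics import MetricsReport, report
from .pyramid import as_image, decompose, make_kernel, reconstruct

logger = logging.getLogger(__name__)

__all__ = ["EnhanceConfig", "enhance", "enhance_file"]


@dataclass(frozen=True)
class EnhanceConfig:
    """Full parameterization of the enhancement pipeline."""

    levels: int = 3
    kernel_a: float = 0.4
    clahe: ClaheParams = field(default_factory=ClaheParams)
    band_clahe: tuple[ClaheParams, ...] | None = None  # optional per-band override
    smooth_sigma: float = 0.5
    se_size: tuple[int, int] = (15, 15)
    gain: GainParams = field(default_factory=GainParams)
    use_clahe: bool = True
    use_morph: bool = True
    use_gain: bool = True
    morph_levels: int = 0  # extra coarsest detail bands to morph-enhance
    output_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if not (0.0 < self.kernel_a < 1.0):
            raise ConfigError("kernel_a must lie in (0, 1)")
        if self.smooth_sigma < 0:
            raise ConfigError("smooth_sigma must be >= 0")
        h, w = self.se_size
        if h < 1 or w < 1 or h % 2 == 0 or w % 2 == 0:
            raise ConfigError(f"se_size must be odd positive integers, got {self.se_size}")
        if self.morph_levels < 0 or self.morph_levels > self.levels:
            raise ConfigError("morph_levels must lie in [0, levels]")
        if self.band_clahe is not None and len(self.band_clahe) != self.levels:
            raise ConfigError("band_clahe must provide one ClaheParams per level")
        lo, hi = self.output_range
        if not hi > lo:
            raise ConfigError("output_range must be increasing")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "levels": self.levels,
            "kernel_a": self.kernel_a,
            "clahe": {
                "tiles": list(self.clahe.tiles),
                "clip_limit": self.clahe.clip_limit,
                "n_bins": self.clahe.n_bins,
                "redistribute": self.clahe.redistribute,
            },
            "smooth_sigma": self.smooth_sigma,
            "se_size": list(self.se_size),
            "gain": {"b": self.gain.b, "c": self.gain.c},
            "use_clahe": self.use_clahe,
            "use_morph": self.use_morph,
            "use_gain": self.use_gain,
            "morph_levels": self.morph_levels,
            "output_range": list(self.output_range),
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "EnhanceConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        known = {
            "levels", "kernel_a", "clahe", "smooth_sigma", "se_size", "gain",
            "use_clahe", "use_morph", "use_gain", "morph_levels", "output_range",
        }
        for key in data:
            if key not in known:
                raise ConfigError(f"unknown config key: {key!r}")
        kwargs: dict = {}
        for key in ("levels", "kernel_a", "smooth_sigma", "use_clahe", "use_morph",
                    "use_gain", "morph_levels"):
            if key in data:
                kwargs[key] = data[key]
        if "se_size" in data:
            kwargs["se_size"] = _pair(data["se_size"], "se_size", int)
        if "output_range" in data:
            kwargs["output_range"] = _pair(data["output_range"], "output_range", float)
        if "clahe" in data:
            sub = data["clahe"]
            if not isinstance(sub, dict):
                raise ConfigError("clahe section must be a mapping")
            sub_known = {"tiles", "clip_limit", "n_bins", "redistribute"}
            for key in sub:
                if key not in sub_known:
                    raise ConfigError(f"unknown config key: 'clahe.{key}'")
            ckw: dict = {}
            if "tiles" in sub:
                ckw["tiles"] = _pair(sub["tiles"], "clahe.tiles", int)
            for key in ("clip_limit", "n_bins", "redistribute"):
                if key in sub:
                    ckw[key] = sub[key]
            try:
                kwargs["clahe"] = ClaheParams(**ckw)
            except ParameterError as exc:
                raise ConfigError(f"invalid clahe section: {exc}") from exc
        if "gain" in data:
            sub = data["gain"]
            if not isinstance(sub, dict):
                raise ConfigError("gain section must be a mapping")
            for key in sub:
                if key not in {"b", "c"}:
                    raise ConfigError(f"unknown config key: 'gain.{key}'")
            try:
                kwargs["gain"] = GainParams(**sub)
            except ParameterError as exc:
                raise ConfigError(f"invalid gain section: {exc}") from exc
        return cls(**kwargs)


def _pair(value, name: str, cast) -> tuple:
    try:
        a, b = value
        return (cast(a), cast(b))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name} must be a pair, got {value!r}") from exc


def _fit_tiles(params: ClaheParams, shape: tuple[int, int]) -> ClaheParams:
    """Cap the tile grid so every tile keeps >= 2 pixels per axis."""
    rows = max(1, min(params.tiles[0], shape[0] // 2))
    cols = max(1, min(params.tiles[1], shape[1] // 2))
    if (rows, cols) != params.tiles:
        return replace(params, tiles=(rows, cols))
    return params


def _fit_se(se_size: tuple[int, int], shape: tuple[int, int]) -> StructuringElement:
    """Cap the SE to the largest odd size fitting the (possibly small) residual."""
    def cap(s: int, d: int) -> int:
        s = min(s, d)
        return s if s % 2 == 1 else s - 1
    return StructuringElement((max(1, cap(se_size[0], shape[0])),
                               max(1, cap(se_size[1], shape[1]))))


def enhance(image, config: EnhanceConfig | None = None) -> np.ndarray:
    """Run the full multiscale enhancement; returns unclipped float output."""
    config = config or EnhanceConfig()
    arr = as_image(image)
    kernel = make_kernel(config.kernel_a)

    t0 = time.perf_counter()
    pyr = decompose(arr, config.levels, kernel)
    logger.info("decompose: levels=%d %.3fs", config.levels, time.perf_counter() - t0)

    bands = list(pyr.bands)
    if config.use_clahe:
        t0 = time.perf_counter()
        for k, band in enumerate(bands):
            params = (config.band_clahe[k] if config.band_clahe is not None
                      else config.clahe)
            bands[k] = equalize_band(band, _fit_tiles(params, band.shape),
                                     config.smooth_sigma)
        logger.info("clahe bands: %.3fs", time.perf_counter() - t0)

    residual = pyr.residual
    if config.use_morph:
        t0 = time.perf_counter()
        residual = morph_enhance(residual, _fit_se(config.se_size, residual.shape))
        for k in range(config.levels - config.morph_levels, config.levels):
            bands[k] = morph_enhance(bands[k], _fit_se(config.se_size, bands[k].shape))
        logger.info("morphology: %.3fs", time.perf_counter() - t0)

    out = reconstruct(
        replace_pyramid(pyr, bands, residual), kernel
    )
    if config.use_gain:
        out = apply_gain(out, config.gain)
    return out


def replace_pyramid(pyr, bands, residual):
    """Shallow copy of a pyramid with new bands/residual."""
    from .pyramid import LaplacianPyramid

    return LaplacianPyramid(bands=bands, residual=residual,
                            original_shape=pyr.original_shape)


def enhance_file(in_path, out_path, config: EnhanceConfig | None = None,
                 report_path=None) -> MetricsReport:
    """Read an image file, enhance it, write the result; optional metrics report.

    Output is clipped to the configured range and written at the source bit
    depth.  The report compares the clipped output against the input and logs
    the effective parameter set.
    """
    from .io import read_image, write_image

    config = config or EnhanceConfig()
    logger.info("effective config: %s", json.dumps(config.to_dict()))
    loaded = read_image(in_path)
    out = enhance(loaded.grid, config)
    lo, hi = config.output_range
    clipped = np.clip(out, lo, hi)
    write_image(clipped, out_path, bit_depth=loaded.source_bit_depth)

    rep = report(clipped, loaded.grid, method="enhanced")
    rep.extras["parameters"] = config.to_dict()
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
    return rep
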