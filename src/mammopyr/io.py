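"""Image readers/writers and configuration files.

Grayscale PNG and TIFF at 8 or 16 bits are the supported formats (DICOM read
is available when pydicom is installed).  On load, integer codes are
normalized to [0, 1] floats as value / (2^bit_depth - 1); on write, floats
are clipped to [0, 1] and quantized with round-half-up,
round(v * (2^d - 1)) = floor(v * (2^d - 1) + 0.5), which is platform-stable
(no banker's rounding).  A write-then-read round trip is exact at the same
bit depth.

Configuration files are YAML (JSON is a YAML subset) mirroring EnhanceConfig;
unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigError, ImageIOError, ParameterError
from .pipeline import EnhanceConfig

__all__ = ["LoadedImage", "read_image", "write_image", "load_config", "save_config"]

_PNG_EXT = {".png"}
_TIFF_EXT = {".tif", ".tiff"}
_DICOM_EXT = {".dcm", ".dicom"}

# ITU-R BT.709 luma weights, used only with to_gray=True
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class LoadedImage:
    """A grayscale image normalized to [0, 1] plus its source characteristics."""

    grid: np.ndarray
    source_bit_depth: int
    source_format: str
    path: str


def read_image(path, to_gray: bool = False) -> LoadedImage:
    """Read a grayscale PNG/TIFF (or DICOM) file, normalized to [0, 1] floats.

    Multi-channel input is rejected unless to_gray=True, in which case it is
    luminance-converted with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    ext = path.suffix.lower()
    if ext in _PNG_EXT:
        fmt = "PNG"
        raw = iio.imread(path)
    elif ext in _TIFF_EXT:
        fmt = "TIFF"
        raw = tifffile.imread(path)
    elif ext in _DICOM_EXT:
        fmt = "DICOM"
        raw = _read_dicom(path)
    else:
        raise ImageIOError(f"unsupported image format {ext!r} (expected PNG, TIFF or DICOM)")

    if raw.ndim == 3:
        if not to_gray:
            raise ImageIOError(
                f"{path} has {raw.shape[-1]} channels; pass to_gray=True to convert"
            )
        warnings.warn(f"{path}: converting multi-channel image to luminance")
        raw = raw[..., :3] @ _LUMA
        raw = raw.astype(np.float64)
    if raw.ndim != 2:
        raise ImageIOError(f"{path}: expected a 2-D grayscale image, got shape {raw.shape}")

    if raw.dtype == np.uint8:
        depth = 8
    elif raw.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(raw.dtype, np.floating):
        depth = 16  # already continuous; keep values, write back at 16 bits
        return LoadedImage(np.asarray(raw, dtype=np.float64), depth, fmt, str(path))
    else:
        raise ImageIOError(f"{path}: unsupported dtype {raw.dtype}")
    grid = raw.astype(np.float64) / (2 ** depth - 1)
    return LoadedImage(grid, depth, fmt, str(path))


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImageIOError("DICOM support requires the pydicom package") from exc
    ds = pydicom.dcmread(path)
    return np.asarray(ds.pixel_array)


def write_image(grid, path, bit_depth: int = 8) -> None:
    """Clip to [0, 1], quantize round-half-up at bit_depth, write by extension."""
    arr = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("cannot write non-finite values")
    if bit_depth not in (8, 16):
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    maxcode = 2 ** bit_depth - 1
    codes = np.floor(np.clip(arr, 0.0, 1.0) * maxcode + 0.5)
    codes = np.clip(codes, 0, maxcode)
    out = codes.astype(np.uint8 if bit_depth == 8 else np.uint16)

    path = Path(path)
    ext = path.suffix.lower()
    if ext in _PNG_EXT:
        iio.imwrite(path, out)
    elif ext in _TIFF_EXT:
        tifffile.imwrite(path, out)
    else:
        raise ImageIOError(f"unsupported output format {ext!r} (expected PNG or TIFF)")


def load_config(path) -> EnhanceConfig:
    """Load and validate a YAML/JSON pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        data = {}
    try:
        return EnhanceConfig.from_dict(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: EnhanceConfig, path) -> None:
    """Write a pipeline configuration as YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
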