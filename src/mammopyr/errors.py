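"""Exception hierarchy shared by all mammopyr modules."""


class MammopyrError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MammopyrError, ValueError):
    """A parameter is outside its documented domain."""


class ShapeError(MammopyrError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class DecompositionDepthError(MammopyrError, ValueError):
    """Requested pyramid depth exceeds what the image size supports."""


class PyramidIntegrityError(MammopyrError, ValueError):
    """A pyramid's shape chain is internally inconsistent."""


class DegenerateInputError(MammopyrError, ValueError):
    """Input is degenerate for this operation (empty image, empty histogram, ...)."""


class UndefinedMetricError(MammopyrError, ZeroDivisionError):
    """A metric is mathematically undefined for this input (e.g. zero denominator)."""


class ConfigError(MammopyrError, ValueError):
    """A configuration file or mapping violates the schema."""


class ImageIOError(MammopyrError, OSError):
    """An image file could not be read or written."""
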