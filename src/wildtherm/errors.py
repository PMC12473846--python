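"""Exception hierarchy shared across the package."""


class WildthermError(Exception):
    """Base class for all package errors."""


class FormatError(WildthermError):
    """Unsupported image format or bit depth."""


class ParameterError(WildthermError, ValueError):
    """Invalid operator or pipeline parameter."""


class BoundsError(WildthermError, ValueError):
    """Geometry (ROI, region) outside image bounds."""


class ShapeError(WildthermError, ValueError):
    """Mismatched image dimensions."""


class EmptyInputError(WildthermError, ValueError):
    """No frames / empty sequence where at least one is required."""


class AmbiguityError(WildthermError, ValueError):
    """Input ordering cannot be resolved deterministically."""


class DataError(WildthermError, ValueError):
    """Inconsistent tabular input (e.g. missing ground-truth row)."""


class ConfigurationError(WildthermError, ValueError):
    """Invalid or incomplete run configuration."""
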