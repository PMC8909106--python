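"""Exception hierarchy shared across the package."""


class LbcScreenError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(LbcScreenError, ValueError):
    """A tile or coordinate falls outside the slide."""


class InvalidAnnotationError(LbcScreenError, ValueError):
    """An annotation polygon is degenerate or malformed."""


class AnnotationParseError(LbcScreenError, ValueError):
    """An annotation file could not be parsed; message carries context."""


class ConfigError(LbcScreenError, ValueError):
    """An invalid configuration value or combination."""


class GeometryError(LbcScreenError, ValueError):
    """Mismatched tile lattices or incompatible raster geometry."""
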