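"""Exception types shared across the package."""


class PluckSegError(Exception):
    """Base class for all pluckseg errors."""


class GridCompatibilityError(PluckSegError, ValueError):
    """Two grids that must share shape and class set do not."""


class ChannelCountError(PluckSegError, ValueError):
    """An image does not have exactly three colour channels."""


class DecompositionDepthError(PluckSegError, ValueError):
    """The image is too small for the requested wavelet depth."""


class StencilGeometryError(PluckSegError, ValueError):
    """Stencil offsets collide after rounding, or the geometry is invalid."""


class LocationError(PluckSegError, ValueError):
    """A query location is outside the foreground."""


class DegenerateMaskError(PluckSegError, ValueError):
    """A foreground mask required to be non-empty is empty."""


class LabelRangeError(PluckSegError, ValueError):
    """A label value falls outside {0..K}."""


class EmptyPoolError(PluckSegError, ValueError):
    """No candidate label maps remain after exclusion."""


class StratificationError(PluckSegError, ValueError):
    """A class has no foreground cells anywhere in the training pool."""


class MissingAtlasError(PluckSegError, ValueError):
    """The variant requires atlas context features but no atlas was supplied."""


class FeatureSanityError(PluckSegError, ValueError):
    """A feature block contains non-finite values."""


class LayoutError(PluckSegError, ValueError):
    """A synthetic pluck cannot be laid out on the requested grid."""


class ConfigError(PluckSegError, ValueError):
    """A run configuration failed schema validation."""
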