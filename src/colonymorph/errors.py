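"""Exception hierarchy for the macrocolony analysis pipeline."""


class ColonyMorphError(Exception):
    """Base class for all errors raised by colonymorph."""


class ImageReadError(ColonyMorphError):
    """An image file could not be read."""


class UnsupportedFormatError(ImageReadError):
    """The image format needs an optional reader that is not installed."""


class LayoutError(ColonyMorphError):
    """An experiment layout table is malformed or violates an invariant."""


class SegmentationError(ColonyMorphError):
    """No colony contour could be extracted from an image."""


class DegenerateImageError(ColonyMorphError):
    """The image has no intensity contrast to threshold (e.g. constant)."""


class GeometryError(ColonyMorphError):
    """A geometric precondition failed (tangent line, degenerate axis...)."""


class FitError(ColonyMorphError):
    """An ellipse fit failed (too few or collinear points)."""


class DegenerateRegionError(ColonyMorphError):
    """A region mask needed for an intensity statistic is empty."""


class DegenerateStatisticsError(ColonyMorphError):
    """A statistical test is undefined for the given samples."""


class ConfigError(ColonyMorphError):
    """A pipeline configuration is invalid or incomplete."""
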