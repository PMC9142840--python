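"""Exception hierarchy for the nloi package.

All package-specific errors derive from :class:`NloiError` so callers can
catch everything with one clause; subclasses distinguish metadata problems,
channel naming, raster geometry, and degenerate numerical inputs.
"""


class NloiError(Exception):
    """Base class for all nloi errors."""


class MetadataError(NloiError):
    """Required acquisition metadata (pixel size, channel order) is missing."""


class ChannelError(NloiError, KeyError):
    """A channel name is unknown or absent from a frame."""


class ShapeError(NloiError):
    """Rasters that must share a geometry do not."""


class MaskFormatError(NloiError):
    """A label mask file is not an integer-valued single-channel raster."""


class SceneConfigError(NloiError):
    """A synthetic-scene configuration is geometrically impossible."""


class PlacementError(NloiError):
    """Non-overlapping object placement failed within the attempt budget."""


class DegenerateInputError(NloiError):
    """Input carries no usable signal (constant raster, empty collection)."""


class DegenerateSpectrumError(DegenerateInputError):
    """The in-band Fourier power of an image is identically zero."""
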