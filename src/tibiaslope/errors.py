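"""Exception hierarchy.

Recoverable per-slice conditions (an empty slice, an ambiguous curvature
maximum) are signalled with dedicated exception types so the pipeline can
skip the slice and log the reason instead of aborting the subject.
"""


class TibiaSlopeError(Exception):
    """Base class for all errors raised by this package."""


class MetadataError(TibiaSlopeError):
    """Spatial metadata is missing or ambiguous in an input image."""


class SegmentationError(TibiaSlopeError):
    """Automatic thresholding produced an empty or unusable bone mask."""


class EmptySliceError(TibiaSlopeError):
    """The requested slice contains no foreground; caller should skip it."""


class NodeNotFoundError(TibiaSlopeError):
    """No unambiguous plateau rim node on this slice; caller should skip it."""


class ReferenceConstructionError(TibiaSlopeError):
    """Plane 1 / reference slice / reference axis could not be built."""


class PhantomSpecError(TibiaSlopeError):
    """A synthetic-phantom specification is geometrically infeasible."""
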