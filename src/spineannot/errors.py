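"""Exception hierarchy for the annotation pipeline.

Each pipeline stage raises a stage-specific subclass of
:class:`SpineAnnotError` so callers (and the CLI) can report which stage
failed on a given study.
"""


class SpineAnnotError(Exception):
    """Base class for all pipeline errors."""


class MetadataError(SpineAnnotError):
    """A required DICOM attribute is missing or malformed."""


class UnsupportedGeometryError(SpineAnnotError):
    """Non-square image or anisotropic pixel spacing."""


class TopologyError(SpineAnnotError):
    """Spine region is empty, disconnected, or has no traversable path."""


class AnatomyError(SpineAnnotError):
    """Traversal found an anatomically impossible disc/vertebra sequence."""


class GeometryError(SpineAnnotError):
    """Degenerate geometry during height measurement."""


class NormalizationError(SpineAnnotError):
    """Brightness normalization is impossible (e.g. no vertebrae pixels)."""


class TrainingError(SpineAnnotError):
    """Classifier training cannot proceed (e.g. a single class)."""
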