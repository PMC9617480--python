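"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`NeruptureError`, so callers can
distinguish bad configuration from degenerate data without string matching.
"""


class NeruptureError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeruptureError):
    """Invalid geometry, parameters, ROI placement, or config document."""


class FormatError(NeruptureError):
    """An on-disk artifact does not match its declared shape or schema."""


class SchemaError(NeruptureError):
    """A tabular artifact is missing required columns or mixes states."""


class EmptySegmentationError(NeruptureError):
    """No object survived thresholding and the area filter."""


class DegenerateNucleusError(NeruptureError):
    """The nucleus mask erodes to nothing at the requested depth."""


class DegenerateTraceError(NeruptureError):
    """A normalization denominator (baseline, peak, reference) is not positive."""


class InsufficientDataError(NeruptureError):
    """Too few samples to fit the requested model."""
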