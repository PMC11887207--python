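"""Exception hierarchy for the segmentation pipeline."""


class CorosegError(Exception):
    """Base class for all package errors."""


class FormatError(CorosegError):
    """A file could not be parsed or is in an unsupported format."""


class MetadataError(CorosegError):
    """Required image metadata (spacing, direction) is missing or unusable."""


class ContentError(CorosegError):
    """File parsed but its content violates a structural precondition."""


class ParameterError(CorosegError):
    """A user-supplied parameter is out of its valid range."""


class GeometryError(CorosegError):
    """A geometric precondition (shapes, bounds, frames) is violated."""


class MarginError(GeometryError):
    """A requested patch extends beyond the volume bounds."""


class StateError(CorosegError):
    """An operation was called before its required inputs were computed."""


class MetricError(CorosegError):
    """A metric is undefined for the given inputs (e.g. empty surface)."""
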