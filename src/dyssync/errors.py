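"""Exception hierarchy shared across the pipeline."""


class DyssyncError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DyssyncError, ValueError):
    """A configuration or model parameter violates its stated constraints."""


class InvalidGeometryError(DyssyncError, ValueError):
    """A surface or axis is degenerate, open, or self-intersecting."""


class InvalidInputError(DyssyncError, ValueError):
    """A data value (count, volume, table) is outside its valid domain."""


class OutOfDomainError(DyssyncError, ValueError):
    """A point lies outside the region where a field is defined."""


class IndeterminateSDIError(DyssyncError, ValueError):
    """Too few segments have a detectable peak to define the SDI."""


class AlignmentFailureError(DyssyncError, RuntimeError):
    """Slice realignment could not find any overlap to optimize."""


class UndefinedROCError(DyssyncError, ValueError):
    """ROC analysis requires both outcome classes to be present."""
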