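"""Exception hierarchy shared across the package."""


class CycleStateError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CycleStateError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(CycleStateError, ValueError):
    """An input file violates its declared on-disk format."""


class ModelFormatError(FormatError):
    """A model archive is truncated, corrupt, or of an unknown version."""


class UnknownStateError(CycleStateError, ValueError):
    """A requested cell-cycle state is not present."""


class NormalizationError(CycleStateError, ValueError):
    """Normalization preconditions violated (e.g. a cell with zero counts)."""


class AlignmentError(CycleStateError, ValueError):
    """Feature alignment failed (e.g. no overlap with the classifier genes)."""


class ShapeMismatchError(CycleStateError, ValueError):
    """Matrix dimensions do not match the expected feature space."""
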