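"""Named exception hierarchy.

Every malformed input raises a distinct, catchable error type so callers
can tell a missing column from a bad sequence from a platform mix-up.
"""


class ClonotrackError(Exception):
    """Base class for all clonotrack errors."""


class ValidationError(ClonotrackError):
    """Base class for input-validation failures."""


class MissingColumnError(ValidationError):
    """A mandatory column is absent from a table."""


class InvalidSequenceError(ValidationError):
    """A junction contains characters outside {A, C, G, T}, or is empty."""


class NegativeCountError(ValidationError):
    """A read or cell count is negative."""


class DuplicateCloneKeyError(ValidationError):
    """Two clonotypes in one sample share the same clone key."""


class SubsetFractionError(ValidationError):
    """A FACS subset fraction is outside [0, 1] or violates gating logic."""


class EmptySampleError(ClonotrackError):
    """An operation requires a non-empty (or non-zero-read) sample."""


class EmptyCloneSetError(ClonotrackError):
    """An operation requires at least one clone key."""


class PlatformError(ClonotrackError):
    """An operation got a sample from the wrong sequencing platform."""


class SubjectMismatchError(ClonotrackError):
    """Samples that must come from one subject come from several."""


class TissueMismatchError(ClonotrackError):
    """A sample has the wrong tissue for the requested operation."""


class CompartmentError(ClonotrackError):
    """A requested (tissue, subset, timepoint) compartment does not exist."""


class ProvenanceError(ClonotrackError):
    """The simulator's hidden read-provenance channel is required but absent."""
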