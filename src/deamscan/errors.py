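"""Exception hierarchy shared across the package."""


class DeamscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DeamscanError, ValueError):
    """An argument violates a documented precondition."""


class InvalidModelError(DeamscanError, ValueError):
    """A mutation model implies a per-site probability outside [0, 1]."""


class MalformedInputError(DeamscanError, ValueError):
    """An input record is structurally broken (length mismatch, bad FASTQ)."""


class InvalidDesignError(DeamscanError, ValueError):
    """A statistical design cannot be analysed (e.g. a group with <2 replicates)."""


class FitFailureError(DeamscanError, RuntimeError):
    """Nonlinear least squares failed to converge for a named replicate."""


class UndefinedLaneError(DeamscanError, ValueError):
    """A gel lane has zero intensity in both bands."""


class UndefinedRatioError(DeamscanError, ZeroDivisionError):
    """A fold ratio against a zero rate constant."""


class EdgeCaseError(DeamscanError, ValueError):
    """A cleavage rule would produce an empty or full-length fragment."""


class MultiHitError(DeamscanError, ValueError):
    """A clone carries more than one substitution under strict classification."""


class MissingAnnotationError(DeamscanError, KeyError):
    """A mutation call position is not covered by the structure annotation."""


class InvalidCultureError(DeamscanError, ValueError):
    """A culture record with non-positive viable cell count."""
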