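"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 2 usage/validation, 3 data integrity,
4 degenerate or insufficient input.
"""


class QuartetQCError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(QuartetQCError):
    """Input violates a documented precondition (bad label, bad config)."""

    exit_code = 2


class FormatError(ValidationError):
    """A file does not conform to the expected dialect (header, columns)."""


class IntegrityError(QuartetQCError):
    """Duplicate or conflicting records that cannot be silently merged."""

    exit_code = 3


class MissingDataError(QuartetQCError):
    """An operation requiring complete data met missing values."""

    exit_code = 4


class DegenerateInputError(QuartetQCError):
    """Mathematically degenerate input (zero variance, zero noise, one batch)."""

    exit_code = 4


class InsufficientReplicatesError(DegenerateInputError):
    """Fewer replicates than the statistic requires."""


class InsufficientFeaturesError(DegenerateInputError):
    """Fewer metabolites than the operation requires."""


class NotEvaluableError(DegenerateInputError):
    """A metric that cannot be evaluated on this input (reported as missing)."""
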