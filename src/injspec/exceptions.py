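"""Exception hierarchy.

Every error raised by the package derives from :class:`InjspecError` so callers
(and the CLI) can catch one base class; subclasses mirror the distinct failure
modes of the pipeline (schema vs. integrity vs. statistical degeneracy, ...).
"""


class InjspecError(Exception):
    """Base class for all package errors."""


class SchemaError(InjspecError):
    """An input file is missing a declared column or has an unusable layout."""


class ValidationError(InjspecError):
    """A field value violates its contract (negative deaths, zero population...)."""


class IntegrityError(InjspecError):
    """A table violates a cross-row invariant (duplicate keys, inconsistent denominators)."""


class CoverageError(InjspecError):
    """A required stratum, cause, or year is absent where the operation needs it."""


class AlignmentError(InjspecError):
    """Two series or tables do not share the index the operation requires."""


class DomainError(InjspecError):
    """A scalar argument is outside the mathematical domain of the operation."""


class UndefinedChangeError(DomainError):
    """Percent change requested from a zero (or negative) starting rate."""


class UndefinedProportionError(DomainError):
    """Unspecified proportion requested for a cell with zero all-injury deaths."""


class UndefinedCorrelationError(DomainError):
    """Rank correlation requested for a constant series."""


class InsufficientDataError(InjspecError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(InjspecError):
    """The regression design has no variance (all years equal)."""


class ConfigurationError(InjspecError):
    """A user-supplied configuration references unknown labels or invalid values."""
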