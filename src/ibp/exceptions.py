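"""Exception hierarchy for the profiling pipeline.

Every error raised by this package derives from :class:`IBPError`, so callers
can catch one type at the pipeline boundary.  Data problems (bad CSV, missing
columns, duplicate animals) are distinguished from configuration problems
(unknown profile id, mismatched time points) because the CLI maps them to
different exit codes.
"""


class IBPError(Exception):
    """Base class for all package errors."""


class SchemaError(IBPError):
    """A mandatory column is missing from an input table."""


class ParseError(IBPError):
    """A cell that must be numeric could not be parsed."""


class IntegrityError(IBPError):
    """Duplicate (animal_id, timepoint) rows or inconsistent records."""


class InsufficientDataError(IBPError):
    """Too few observations to compute the requested statistic."""


class ConfigurationError(IBPError):
    """Invalid or contradictory configuration."""


class ProfileLookupError(ConfigurationError):
    """Unknown built-in profile id."""


class DomainError(IBPError, ValueError):
    """An input value lies outside the mathematical domain of a formula."""


class InvalidStateError(IBPError):
    """An operation was applied to an animal in the wrong classification state."""


class MissingInputError(IBPError):
    """A required input (parameter value, flag vector) is absent."""


class DegenerateDataError(IBPError):
    """All groups constant, zero-variance contrasts, or similar degeneracy."""
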