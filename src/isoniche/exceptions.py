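"""Exception hierarchy.

Every error raised by this package derives from :class:`IsonicheError` so
callers (and the CLI, which maps error families onto exit codes) can catch
one base class.
"""


class IsonicheError(Exception):
    """Base class for all package errors."""


class ConfigError(IsonicheError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(IsonicheError):
    """Invalid input data (CLI exit code 3)."""


class SchemaError(DataError):
    """A required column cannot be resolved in an input table."""


class EmptyInputError(DataError):
    """An input table contained no data rows."""


class CalibrationError(DataError):
    """Degenerate two-point calibration (equal standard readings)."""


class DomainError(DataError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class UndefinedIndexError(DomainError):
    """Specialization index undefined (INW + BINW = 0)."""


class GroupingError(DataError):
    """A species is missing from the food-item grouping map."""


class StateError(IsonicheError):
    """An operation was applied to an object in the wrong state."""


class MarginalityError(IsonicheError):
    """An interaction term was requested without both parent main effects."""


class CollinearityError(DataError):
    """Rank-deficient design matrix; message names the aliased columns."""


class NestingError(IsonicheError):
    """Models compared by an F test are not nested."""


class InfeasiblePlanError(DataError):
    """A whisker is too short for the requested segment plan (exit code 4)."""


class JoinError(DataError):
    """Identifier mismatch when joining truth and estimate tables."""
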