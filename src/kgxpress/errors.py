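"""Exception hierarchy shared across the package."""


class KgXpressError(Exception):
    """Base class for all package-specific errors."""


class TableParseError(KgXpressError):
    """A tabular input cell could not be parsed; names the row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class EmptyAnnotationSetError(KgXpressError):
    """An annotation file yielded zero valid records."""


class AmbiguousMappingError(KgXpressError):
    """An identifier maps to more than one distinct target within one map."""

    def __init__(self, message: str, conflicts: list[str] | None = None):
        super().__init__(message)
        self.conflicts = conflicts or []


class CategoryConflictError(KgXpressError):
    """The same node id carries two different semantic categories."""


class GraphValidationError(KgXpressError):
    """A graph violates referential integrity or the closed vocabularies."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class ConfigError(KgXpressError):
    """A synthetic-data configuration violates its own invariants."""
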