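"""Exception hierarchy for dtimf.

All library errors derive from :class:`DtimfError` so callers can catch a
single base class; the subclasses distinguish bad file contents, invalid
domain objects/arguments, and numerical failures inside the solver. The CLI
maps these onto distinct exit codes.
"""


class DtimfError(Exception):
    """Base class for all dtimf errors."""


class FormatError(DtimfError):
    """A file could not be parsed (ragged rows, non-numeric cells, ...)."""


class ValidationError(DtimfError):
    """Parsed data violates a domain invariant (duplicate ids, asymmetry, ...)."""


class DomainError(DtimfError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NumericalError(DtimfError):
    """The solver produced non-finite values; carries block and iteration."""

    def __init__(self, message: str, block: str | None = None,
                 iteration: int | None = None):
        super().__init__(message)
        self.block = block
        self.iteration = iteration


class UndefinedMetricError(DtimfError):
    """A ranking metric is undefined (single-class label set)."""
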