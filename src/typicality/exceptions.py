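"""Exception hierarchy.

``DataError`` subclasses signal problems with the input data or its schema
(CLI exit code 3); ``FitFailed`` signals a classifier that could not be
fitted on the given data (CLI exit code 4), mirroring the "NaN" cells that
density-based one-class methods produce on p >> n tables.
"""


class TypicalityError(Exception):
    """Base class for package errors."""


class DataError(TypicalityError):
    """Problem with input data."""


class SchemaError(DataError):
    """Schema does not cover or match the data columns."""


class ParseError(DataError):
    """A cell could not be parsed as the declared type."""


class MissingDataError(DataError):
    """Missing values under a distance that cannot handle them."""


class IncomparablePairError(DataError):
    """A pair of units shares no observed feature (all Gower weights zero)."""


class FitFailed(TypicalityError):
    """A one-class model could not be fitted (degenerate data, EM collapse...)."""

    def __init__(self, method: str, reason: str):
        self.method = method
        self.reason = reason
        super().__init__(f"{method}: {reason}")
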