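"""Exception hierarchy.

All toolkit errors derive from :class:`CominerError` so callers can catch one
base class; the CLI maps :class:`UsageError` to exit code 2 and
:class:`DataError` (parse/validation/schema failures) to exit code 3.
"""


class CominerError(Exception):
    """Base class for all toolkit errors."""


class UsageError(CominerError):
    """Bad configuration, unknown option, or invalid API usage."""


class DataError(CominerError):
    """Input data failed parsing or validation."""


class ParseError(DataError):
    """Malformed input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(DataError):
    """An invariant violation in otherwise well-formed data."""


class SchemaError(DataError):
    """A tabular or XML input does not match the expected schema."""
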