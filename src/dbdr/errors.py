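"""Exception types shared across the pipeline."""


class DbdrError(Exception):
    """Base class for all package errors."""


class ValidationError(DbdrError):
    """A configuration or input value violates a documented invariant.

    ``field`` names the offending parameter so callers (and the CLI) can
    report it without parsing the message.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(DbdrError):
    """Malformed input data (parse errors, missing labels, bad shapes)."""


class GmtParseError(DataError):
    """A GMT line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")
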