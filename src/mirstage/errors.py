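"""Exception hierarchy for mirstage."""


class MirstageError(Exception):
    """Base class for all package errors."""


class ValidationError(MirstageError):
    """Raised when an input value, record, or configuration is invalid."""


class ParseError(ValidationError):
    """Raised when a file cannot be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)
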