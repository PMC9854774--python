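"""Exception hierarchy shared across bindkin modules."""


class BindkinError(Exception):
    """Base class for all package errors."""

    category = "error"


class InputError(BindkinError, ValueError):
    """A caller-supplied value or object violates a documented precondition."""

    category = "input"


class ParseError(BindkinError, ValueError):
    """A file could not be parsed; carries the offending line where known."""

    category = "parse"

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FitError(BindkinError, RuntimeError):
    """A model fit failed to converge or the data carry no usable signal."""

    category = "fit"
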