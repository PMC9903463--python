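"""Exception hierarchy shared across the package."""


class ColonerError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ColonerError):
    """An unknown label or tag, or a malformed label schema."""


class ValidationError(ColonerError):
    """Input data violates a documented invariant (bad span, overlap, ...)."""


class ParseError(ColonerError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(ColonerError):
    """An invalid configuration value, named explicitly."""


class CorpusTooSmallError(ColonerError):
    """The corpus is empty after min-count filtering."""


class InfeasibleDecodeError(ColonerError):
    """Constrained Viterbi found no feasible tag sequence."""
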