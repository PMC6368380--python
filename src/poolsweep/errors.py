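"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 3.
"""


class PoolsweepError(Exception):
    """Base class for all package errors."""


class ConfigError(PoolsweepError):
    """Invalid configuration (bad parameter values, unknown pool names...)."""


class DataError(PoolsweepError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AnnotationError(DataError):
    """Gene-model inconsistency (CDS outside parent, length not divisible by 3...)."""


class ZeroDepthError(DataError):
    """An allele frequency was requested for a pool with zero read depth."""
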