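"""Exception hierarchy shared by all redcapkit modules."""

from __future__ import annotations


class RedcapKitError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(RedcapKitError):
    """Structural problem in an input file (headers, duplicate fields, ...)."""


class ValidationError(RedcapKitError):
    """Content of an input violates an invariant (unknown column, bad event, ...)."""


class ConfigError(RedcapKitError):
    """Inconsistent or incomplete run configuration."""


class LogicParseError(RedcapKitError):
    """Failure to tokenize or parse a logic/calculation expression.

    ``position`` is the 0-based character offset into the source string.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at offset {position})"
        super().__init__(message)
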