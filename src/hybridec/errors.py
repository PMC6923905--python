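"""Exception hierarchy.

Errors are split into two families so the command line can map them to
distinct exit codes: ``ParameterError`` (bad configuration or arguments,
exit 2) and ``DataError`` (malformed or insufficient input data, exit 3).
"""


class HybridecError(Exception):
    """Base class for all package errors."""


class ParameterError(HybridecError, ValueError):
    """An argument or configuration value is invalid."""


class DataError(HybridecError):
    """Input data is malformed, inconsistent, or insufficient."""


class ParseError(DataError):
    """A sequence or graph file could not be parsed."""


class GraphFormatError(ParseError):
    """A serialized graph file has a bad header or a corrupt line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyGraphError(DataError):
    """No k-mer could be extracted, so a de Bruijn graph cannot be built."""
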