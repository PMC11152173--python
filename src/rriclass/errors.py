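"""Exception types shared across the pipeline."""


class RriclassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RriclassError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RowError(RriclassError, ValueError):
    """A single row of an input file is invalid.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AdapterError(RriclassError, RuntimeError):
    """The external duplex-predictor adapter failed (missing tool, bad exit,
    unparseable output)."""
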