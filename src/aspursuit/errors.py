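"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """Invalid preset, profile, or run configuration."""


class ParseError(ValueError):
    """Malformed trace file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnusableTraceError(ValueError):
    """Trace too short or too incomplete for the requested operation."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested before its upstream artifact exists."""


class DesignCoverageError(ValueError):
    """Analysis requires design cells that are absent from the data."""
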