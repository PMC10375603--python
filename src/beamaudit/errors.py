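"""Exception hierarchy shared across the package."""


class BeamAuditError(Exception):
    """Base class for all errors raised by this package."""


class ScanFormatError(BeamAuditError):
    """Malformed scan file: missing header keys, unparseable numbers."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(BeamAuditError):
    """Domain-object invariant violated."""


class AnalysisError(BeamAuditError):
    """A metric could not be computed from the given input."""
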