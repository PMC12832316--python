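"""Exception hierarchy shared across the pipeline.

The split mirrors the CLI exit-code contract: configuration problems
(:class:`ValidationError`, exit 2), malformed or inconsistent input data
(:class:`DataError`, exit 3), and optimizer failures
(:class:`ConvergenceError`, exit 4).
"""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class ValidationError(PvSignalError):
    """A configuration or precondition problem detected before any work."""


class DataError(PvSignalError):
    """Malformed or internally inconsistent input data."""


class SchemaError(DataError):
    """An input table is missing mandatory columns or has unparseable lines."""


class UnmappedTermError(DataError):
    """A preferred term has no system-organ-class mapping in the dictionary."""

    def __init__(self, terms):
        self.terms = sorted(set(terms))
        super().__init__(
            f"{len(self.terms)} preferred term(s) missing from the PT->SOC "
            f"dictionary: {', '.join(self.terms[:10])}"
            + ("..." if len(self.terms) > 10 else "")
        )


class ConvergenceError(PvSignalError):
    """An iterative fit failed to converge; carries the optimizer result."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result
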