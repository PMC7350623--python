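"""Exception hierarchy shared across the package."""


class CnssigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CnssigError):
    """A configuration object violates one of its invariants."""


class RCCParseError(CnssigError):
    """An RCC file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number at which the problem was detected.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ClassificationIntegrityError(CnssigError):
    """A reference sample was not assigned to its own entity.

    Raised by group calling: if a molecularly pre-diagnosed reference tumor
    does not recover its own diagnosis, the run cannot be trusted and no
    calls are returned.
    """


class PipelineError(CnssigError):
    """A pipeline stage failed; partial outputs carry a ``.failed`` marker."""
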