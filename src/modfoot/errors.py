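"""Exception and warning types shared across the package."""


class ModfootError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ModfootError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ModfootError, ValueError):
    """A record violates a data-model invariant.

    Carries the 1-based line number of the offending record when the
    error originates from a file.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class InsufficientDataError(ModfootError, ValueError):
    """Too few observations for the requested fit or test."""


class DegenerateFitError(ModfootError, ValueError):
    """The input admits no meaningful fit (e.g. all values identical)."""


class NoBoundaryError(ModfootError, ValueError):
    """No density crossing exists between the mixture component means.

    Choose a cut-off manually (``fixed_cutoff``) when this is raised.
    """


class DataQualityWarning(UserWarning):
    """Recoverable data-quality issue (duplicates, empty output, ...)."""
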