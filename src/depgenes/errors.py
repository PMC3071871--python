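"""Exception hierarchy shared across the package."""


class DepgenesError(Exception):
    """Base class for all package errors."""


class FormatError(DepgenesError):
    """An input file does not have the expected layout."""


class ValidationError(DepgenesError):
    """Input values violate a documented invariant."""


class ConfigurationError(DepgenesError):
    """A configuration file or parameter set is internally inconsistent."""


class NoMatrixPassedError(DepgenesError):
    """No weight matrix satisfied the core-gene selection criterion.

    Carries the best near-misses so callers can report how far off the
    closest matrices were.
    """

    def __init__(self, message: str, near_misses=()):
        super().__init__(message)
        self.near_misses = tuple(near_misses)
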