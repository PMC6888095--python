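"""Exception hierarchy shared across the package."""


class RenyiTEError(Exception):
    """Base class for all package-specific errors."""


class InputError(RenyiTEError, ValueError):
    """Malformed or non-finite input data."""


class ParameterError(RenyiTEError, ValueError):
    """An estimator or model parameter outside its valid range."""


class DegenerateDataError(RenyiTEError, ValueError):
    """Data without the variability an operation requires (e.g. constant series)."""


class InsufficientDataError(RenyiTEError, ValueError):
    """Too few samples remain after embedding/alignment."""


class GenerationError(RenyiTEError, RuntimeError):
    """A simulator failed to produce valid output (e.g. no stable model found)."""


class ParseError(RenyiTEError, ValueError):
    """A data file could not be parsed."""
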