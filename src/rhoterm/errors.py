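"""Exception hierarchy shared across the analysis stages."""


class RhotermError(Exception):
    """Base class for all package errors."""


class ValidationError(RhotermError):
    """Input violates a documented invariant (bad alphabet, nonpositive Ct, ...)."""


class ParseError(RhotermError):
    """A file could not be parsed; the message names the offending record."""


class CoordinateError(RhotermError):
    """A region lies outside its contig or is otherwise inconsistent."""


class TooShortError(RhotermError):
    """A sequence or interval is shorter than the sliding window requires."""


class ConfigurationError(RhotermError):
    """A required coordinate, path or option is missing or inconsistent."""


class PairingError(RhotermError):
    """A mutant measurement has no wild-type baseline to pair against."""


class InsufficientDataError(RhotermError):
    """Too few points survive a gate (or are supplied) for the requested fit."""


class DegenerateDesignError(RhotermError):
    """The regression design matrix is singular (e.g. constant x)."""
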