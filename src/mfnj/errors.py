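"""Exception hierarchy for the mfnj package."""


class MfnjError(Exception):
    """Base class for all package-specific errors."""


class MatrixParseError(MfnjError, ValueError):
    """Raised when a distance-matrix file cannot be parsed."""


class MatrixValidationError(MfnjError, ValueError):
    """Raised when parsed values violate distance-matrix invariants."""


class InputError(MfnjError, ValueError):
    """Raised for invalid algorithm inputs (e.g. fewer than two taxa)."""
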