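"""Exception hierarchy for the comsli package."""


class ComsliError(Exception):
    """Base class for all comsli errors."""


class FormatError(ComsliError):
    """Raised when an input file or image stack is malformed."""


class ValidationError(ComsliError):
    """Raised when inputs violate a documented contract."""


class CalibrationError(ComsliError):
    """Raised when a diffuser stack cannot yield a valid flat-field."""
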