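"""Package exception hierarchy.

``ValidationError`` marks bad arguments or malformed inputs (CLI exit 2);
``EstimationError`` marks data from which the requested quantity cannot be
estimated (CLI exit 3).
"""


class TelquantError(Exception):
    """Base class for all package errors."""


class ValidationError(TelquantError, ValueError):
    """Invalid argument, unit, or input table."""


class EstimationError(TelquantError, RuntimeError):
    """Estimation is undefined or failed on the supplied data."""
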