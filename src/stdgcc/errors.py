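"""Exception types shared across the package."""


class StdgccError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StdgccError):
    """Input data violates a structural contract (e.g. negative counts)."""


class AlignmentError(StdgccError):
    """Barcodes cannot be aligned across counts / coordinates / labels."""


class ParameterError(StdgccError):
    """A user-supplied parameter is outside its admissible range."""


class EmptyResultError(StdgccError):
    """A filtering step removed everything."""


class DegenerateGraphError(StdgccError):
    """The spatial graph has a zero-degree row and cannot be normalized."""


class NumericalInstabilityError(StdgccError):
    """Non-finite values appeared during the forward pass or training."""
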