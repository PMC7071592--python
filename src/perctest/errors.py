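"""Package exception hierarchy."""


class PerctestError(Exception):
    """Base class for package errors."""


class InputDataError(PerctestError):
    """Raised when user-supplied data cannot be ingested."""


class ComputationError(PerctestError):
    """Raised when a numerical routine fails to converge or find a solution."""
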