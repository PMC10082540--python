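"""Exception types shared across the package."""


class InputValidationError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


class FittingError(RuntimeError):
    """Raised when model fitting cannot proceed (e.g. a zero-likelihood site)."""
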