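"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input object violates a documented precondition."""


class RangeError(ValidationError):
    """Raised when a coordinate or value falls outside its valid range."""
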