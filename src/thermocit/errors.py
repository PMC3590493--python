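"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is formally valid but makes the requested computation singular
    (zero variance, singular normal equations, ...)."""


class ParseError(ValueError):
    """A file does not conform to the expected format."""
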