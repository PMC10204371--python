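"""Exception types shared across the package."""


class VfoaBetaError(Exception):
    """Base class for package errors."""


class InvalidInputError(VfoaBetaError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateImageError(InvalidInputError):
    """An image has no gray-level spread (constant), so min/max
    normalization is undefined."""
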