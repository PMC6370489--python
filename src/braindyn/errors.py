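"""Exception types shared across the package."""


class BraindynError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(BraindynError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(BraindynError, ValueError):
    """Input is structurally valid but degenerate (e.g. constant series)."""


class IntegrationError(BraindynError, RuntimeError):
    """Numerical integration produced a non-finite or unphysical state."""


class MatrixParseError(BraindynError, ValueError):
    """A matrix file could not be parsed."""
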