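"""Exception hierarchy shared across the codec."""


class FracVQError(Exception):
    """Base class for all fracvq errors."""


class ConfigurationError(FracVQError, ValueError):
    """An operation was configured with invalid parameters."""


class SizeError(FracVQError, ValueError):
    """An input image/band has a shape the operation cannot handle."""


class DegenerateInputError(FracVQError, ValueError):
    """Input carries no usable variation (constant values, zero energy)."""


class InfeasibleCodebookError(FracVQError, ValueError):
    """A codebook was requested with more codewords than training blocks."""


class ContainerError(FracVQError, ValueError):
    """An encoded container is corrupt, truncated, or inconsistent."""
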