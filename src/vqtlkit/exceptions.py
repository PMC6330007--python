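"""Exception types shared across the toolkit."""


class VqtlError(Exception):
    """Base class for all vqtlkit errors."""


class InvalidArgumentError(VqtlError, ValueError):
    """An input violates a documented precondition (bad shape, domain, or kind)."""


class NumericalError(VqtlError, ArithmeticError):
    """A computation failed numerically (non-finite objective, singular system)."""


class FormatError(VqtlError, ValueError):
    """A file does not conform to the expected TSV schema."""
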