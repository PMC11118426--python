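"""Exception hierarchy shared across the package."""


class SeqGaugeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SeqGaugeError, ValueError):
    """A model specification, parameter table or input file is invalid."""


class EnumerationCapError(SeqGaugeError):
    """Full sequence enumeration was requested for a space larger than the cap."""

    def __init__(self, alpha: int, length: int, cap: int):
        self.alpha = alpha
        self.length = length
        self.cap = cap
        super().__init__(
            f"sequence space has {alpha}^{length} = {alpha**length} elements, "
            f"exceeding the enumeration cap of {cap}"
        )
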