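"""Exception hierarchy for mcscore."""


class McscoreError(Exception):
    """Base class for all mcscore errors."""


class ValidationError(McscoreError):
    """Input values violate a documented contract (range, uniqueness, shape)."""


class DegenerateInputError(McscoreError):
    """Input is structurally unusable: too few values, zero variance, empty family."""


class InsufficientDataError(McscoreError):
    """A statistical model cannot be fitted from the data provided (e.g. one sex absent)."""
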