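"""Exception hierarchy shared across the package."""


class RankProductError(Exception):
    """Base class for all rpval-specific errors."""


class SizeGuardError(RankProductError):
    """A computation was refused because it exceeds a configured size guard."""


class NumericRangeError(RankProductError):
    """A quantity (typically n**k) falls outside the supported floating range."""


class DataError(RankProductError):
    """Malformed or inconsistent input data."""
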