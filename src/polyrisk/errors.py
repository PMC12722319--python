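"""Exception types raised by the package."""


class PolyriskError(Exception):
    """Base class for all package-specific errors."""


class CIFParseError(PolyriskError, ValueError):
    """A CIF document is missing required tags or contains malformed values."""


class InvalidCellError(PolyriskError, ValueError):
    """Unit-cell parameters do not describe a valid lattice."""


class UndefinedSimilarityError(PolyriskError, ValueError):
    """Similarity is undefined, e.g. for an all-zero pattern."""


class InfiniteGapError(PolyriskError, ValueError):
    """An occupancy of exactly 0 or 1 implies an infinite energy gap."""
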