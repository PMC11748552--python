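"""Exception hierarchy shared across the pipeline stages."""


class ImodkitError(Exception):
    """Base class for all imodkit errors."""


class SizingError(ImodkitError):
    """Requested module/regulon sizes cannot fit in the gene universe."""


class ConfigurationError(ImodkitError):
    """Invalid option value (unknown label, empty grid, bad threshold...)."""


class ShapeError(ImodkitError):
    """Matrix dimensions do not conform."""


class DimensionError(ImodkitError):
    """Requested ICA dimension exceeds the rank of the input."""


class IncompatibilityError(ImodkitError):
    """Inputs share no common gene universe."""


class IdentifierError(ImodkitError):
    """Unknown or duplicated sample/gene identifier."""


class DegeneracyError(ImodkitError):
    """Degenerate input (constant matrix, zero norm, all-equal weights)."""


class SizeError(ImodkitError):
    """Input too small for the statistic to be defined."""


class UniverseError(ImodkitError):
    """Gene set member not contained in the declared universe."""


class UndefinedCorrelationError(ImodkitError):
    """Correlation undefined because one input has zero variance."""


class ParseError(ImodkitError):
    """Malformed on-disk artifact."""
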