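"""Exception hierarchy shared across pipeline stages."""


class RnaDriverError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RnaDriverError):
    """Invalid simulation or filter configuration."""


class FormatError(RnaDriverError):
    """Malformed input record (bad nucleotide string, missing context, ...)."""


class PairingError(RnaDriverError):
    """Sample identifiers of two tables that must pair do not match."""


class AnnotationError(RnaDriverError):
    """A gene referenced by a record is absent from the gene catalog."""


class StatisticsError(RnaDriverError):
    """A statistical routine received degenerate input (empty group, zero variance)."""


class NormalizationError(RnaDriverError):
    """A normalization step cannot be applied (all-zero column, ...)."""


class ConfoundingError(RnaDriverError):
    """Batch labels perfectly confounded with the biological grouping."""


class DimensionError(RnaDriverError):
    """Requested embedding dimension incompatible with the sample count."""


class GroupingError(RnaDriverError):
    """A marker-based sample split produced an empty group."""


class InputError(RnaDriverError):
    """Generic invalid input to an analysis operation."""
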