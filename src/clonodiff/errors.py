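"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3.
"""


class ClonodiffError(Exception):
    """Base class for all package errors."""


class ConfigError(ClonodiffError):
    """Invalid configuration (bad schema, unknown keys, invalid priors)."""


class DataError(ClonodiffError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A table is missing mandatory columns or contains malformed cells."""


class EmptyRepertoireError(DataError):
    """A repertoire with zero usable clonotypes where one is required."""


class EmptySelectionError(DataError):
    """A selection (e.g. all CDR3s of a given length) matched nothing."""


class GeneNameError(DataError):
    """A gene name without a recognizable locus prefix."""


class LocusMismatchError(DataError):
    """A gene call whose locus prefix contradicts the declared locus."""


class InsufficientReplicationError(DataError):
    """A group comparison was requested with fewer than two samples per group."""


class NormalizationError(DataError):
    """A frequency vector that does not sum to one beyond tolerance."""


class BoundsError(DataError):
    """A rank/window size k exceeding the number of available items."""
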