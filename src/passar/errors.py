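"""Exception hierarchy for :mod:`passar`.

Every user-facing failure mode raises a distinct, named subclass of
:class:`PassarError` so callers (and the CLI) can react selectively.
"""


class PassarError(Exception):
    """Base class for all passar errors."""


class MissingFileError(PassarError, FileNotFoundError):
    """An input file does not exist."""


class DuplicateIDError(PassarError):
    """A sample or taxon identifier occurs more than once."""


class NegativeCountError(PassarError):
    """A count cell is negative."""


class NonIntegerCountError(PassarError):
    """A count cell is not an integer (or not numeric at all)."""


class EmptyTableError(PassarError):
    """A table (or a required sample/class) has no usable counts."""


class UnknownSampleError(PassarError, KeyError):
    """A referenced sample identifier is absent from the table."""


class MissingAreaError(PassarError, KeyError):
    """A sample has no area assigned."""


class InvalidSpecError(PassarError, ValueError):
    """A specification object violates its invariants."""


class TaxonTreeMismatchError(PassarError):
    """A taxon with positive count has no matching leaf in the tree."""


class ConfigError(PassarError, ValueError):
    """A pipeline configuration is inconsistent or incomplete."""
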