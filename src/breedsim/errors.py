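"""Exception hierarchy.

Everything raised on bad user input derives from :class:`BreedsimError`, so
callers (and the CLI) can catch one type. Validation errors additionally
derive from ``ValueError`` and lookup errors from ``KeyError`` to keep
idiomatic ``except`` clauses working.
"""


class BreedsimError(Exception):
    """Base class for all errors raised by breedsim."""


class MapSchemaError(BreedsimError, ValueError):
    """A required column is missing from a linkage-map table."""


class TraitLookupError(BreedsimError, KeyError):
    """A requested trait name is not a column of the linkage map."""


class ValidationError(BreedsimError, ValueError):
    """Data violates an invariant (range, sortedness, binarity, ...)."""


class DimensionError(ValidationError):
    """Array shapes or marker counts do not agree."""


class PhasingError(ValidationError):
    """Genotype input is not phased; phased haplotypes are required."""


class ConfigurationError(BreedsimError, ValueError):
    """A simulator or schema configuration is invalid or incomplete."""
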