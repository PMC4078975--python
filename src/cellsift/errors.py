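"""Exception hierarchy for cellsift."""


class CellSiftError(Exception):
    """Base class for all cellsift errors."""


class ConfigurationError(CellSiftError):
    """An invalid configuration value (counts, sizes, fractions, seeds)."""


class ValidationError(CellSiftError):
    """Input data violates a documented contract (shapes, labels, tables)."""


class DataError(CellSiftError):
    """A dataset is degenerate for the requested operation (empty class,
    no non-zero descriptors, all-zero design matrix, ...)."""
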