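"""Exception hierarchy for dataset validation and analysis."""


class DupfatesError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DupfatesError):
    """An input table is missing a required column or has a malformed header."""


class IntegrityError(DupfatesError):
    """Referential or uniqueness violation (unknown gene id, duplicate gene id)."""


class TableValueError(DupfatesError, ValueError):
    """A cell value is out of range (negative expression, negative dN, ...)."""


class ConfigurationError(DupfatesError):
    """A synthetic-data configuration is invalid or infeasible."""


class TabulationError(DupfatesError):
    """A group has no flag-bearing genes, so a proportion cannot be formed."""


class DegenerateProportionsError(DupfatesError):
    """Pooled proportion is 0 or 1: the Z statistic has zero variance."""
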