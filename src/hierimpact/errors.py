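"""Exception hierarchy shared across the package."""


class HierImpactError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HierImpactError):
    """Input data violates a structural requirement (cycle, dangling edge, schema)."""


class LookupError_(HierImpactError, KeyError):
    """A referenced concept or edge does not exist in the graph/index."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class ConfigurationError(HierImpactError):
    """A configuration value (vocabulary label, argument range) is invalid."""


class PreconditionError(HierImpactError):
    """A defect relation violates the structural precondition of its metric."""


class DegenerateInputError(HierImpactError):
    """Statistical test undefined for the given input (all NA or all null-valued)."""


class GenerationError(HierImpactError):
    """Synthetic-data generation could not satisfy its constraints."""
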