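"""Exception hierarchy shared across the package."""


class BeesemError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BeesemError, ValueError):
    """A table is missing a mandatory column or a cell cannot be parsed."""


class TableValidationError(BeesemError, ValueError):
    """A parsed table violates one of its declared invariants."""


class DomainError(BeesemError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateInputError(BeesemError, ValueError):
    """Input with zero variance (or otherwise collapsed) where spread is required."""


class InsufficientDataError(BeesemError, ValueError):
    """Too few observations for the requested statistic."""


class ModelError(BeesemError, ValueError):
    """A causal model definition is invalid (cyclic, dangling edge, ...)."""


class ConfigError(BeesemError, ValueError):
    """A run or generator configuration is inconsistent or infeasible."""
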