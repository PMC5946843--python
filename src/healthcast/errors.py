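"""Exception hierarchy for the healthcast pipeline."""


class HealthcastError(Exception):
    """Base class for all package errors."""


class SchemaError(HealthcastError):
    """A required column is missing or cannot be mapped to a canonical name."""


class PanelValidationError(HealthcastError):
    """A country-year panel violates a data-model invariant."""


class ConfigError(HealthcastError):
    """An invalid configuration value (dimension, horizon, seed, threshold...)."""


class FitError(HealthcastError):
    """Model estimation failed (rank deficiency, non-convergence...)."""


class PoolingError(HealthcastError):
    """Ensemble pooling was asked to operate on an empty retained set."""


class GenerationError(HealthcastError):
    """The synthetic-data generator cannot satisfy its postconditions."""


class AllocationError(HealthcastError):
    """Recipient shares do not form a valid allocation."""


class AggregationError(HealthcastError):
    """Grouping labels are missing or inconsistent during aggregation."""


class ComputationError(HealthcastError):
    """A derived quantity is undefined for the given inputs."""
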