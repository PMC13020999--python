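"""Exception types shared across the package."""


class DualNoiseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DualNoiseError):
    """Invalid task, model, or inference configuration."""


class GenerationError(DualNoiseError):
    """Session generation could not satisfy its constraints."""


class DataError(DualNoiseError):
    """A trial table or derived table violates its contract."""


class UndefinedStatisticError(DualNoiseError):
    """A statistic has no eligible observations (distinct from zero)."""
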