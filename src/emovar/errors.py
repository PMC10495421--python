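"""Exception hierarchy for the emovar pipeline."""


class EmovarError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmovarError, ValueError):
    """A configuration object violates its invariants."""


class GenerationError(EmovarError, RuntimeError):
    """Synthetic-data generation could not satisfy its contract."""


class SimulationError(EmovarError, RuntimeError):
    """A panel simulation was refused (e.g. non-stationary dynamics)."""


class EstimationError(EmovarError, RuntimeError):
    """Design construction or FGLS estimation failed."""


class ReductionError(EmovarError, RuntimeError):
    """Factor reduction of the appraisal survey failed."""


class MissingDataError(EmovarError, ValueError):
    """A day inside the panel span has no documents."""


class DomainError(EmovarError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
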