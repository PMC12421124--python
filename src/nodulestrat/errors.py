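"""Exception hierarchy for cohort parsing, validation and analysis."""


class NoduleStratError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NoduleStratError):
    """A cohort file does not conform to the documented column schema."""


class CohortValidationError(NoduleStratError):
    """A record violates a domain invariant (row-level where applicable)."""


class InfeasibleSpecError(NoduleStratError):
    """A marginal-count specification cannot be realised by any cohort."""


class ConfigurationError(NoduleStratError):
    """A protocol or pipeline configuration is incomplete or inconsistent."""


class ConvergenceError(NoduleStratError):
    """A model fit failed to converge (e.g. perfect separation in a logistic fit)."""
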