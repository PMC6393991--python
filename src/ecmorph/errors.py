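"""Exception hierarchy shared across the package."""


class EcmorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcmorphError, ValueError):
    """An input violates a documented precondition (shape, range, schema)."""


class DegenerateInputError(EcmorphError, ValueError):
    """An input is structurally valid but the quantity is undefined on it
    (empty collagen mask, empty tissue mask, ...)."""


class CohortEmptyError(EcmorphError, RuntimeError):
    """Every record of a cohort manifest failed to load."""


class InsufficientDataError(EcmorphError, ValueError):
    """Too few observations for the requested statistic."""


class FixtureGenerationError(EcmorphError, RuntimeError):
    """A synthetic-fixture spec could not be realized within bounded attempts."""
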