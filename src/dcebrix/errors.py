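"""Exception hierarchy shared across the pipeline."""


class DcebrixError(Exception):
    """Base class for all pipeline errors."""


class InsufficientDataError(DcebrixError):
    """Too few samples for the requested operation."""


class NoArrivalError(DcebrixError):
    """No measurement ever exceeded the bolus-arrival threshold."""


class BaselineContaminationError(DcebrixError):
    """Bolus arrived inside the baseline window; baseline average is invalid."""


class FitFailureError(DcebrixError):
    """Curve fit failed to converge from every start."""


class InvalidQuartilesError(DcebrixError):
    """Quartile triple violates q1 < median < q3 (or positivity for lognormal)."""


class UndefinedROCError(DcebrixError):
    """ROC requested with only one class present."""


class SchemaError(DcebrixError):
    """Input table is missing required columns."""


class DataError(DcebrixError):
    """Input table contains malformed rows."""


class ConfigError(DcebrixError):
    """Simulation or run configuration violates an invariant."""
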