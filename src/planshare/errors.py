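"""Exception types shared across the pipeline."""


class PlanshareError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PlanshareError):
    """A configuration value violates its contract (e.g. mixture not summing to 1)."""


class InvalidInputError(PlanshareError):
    """An input table or array violates a precondition of an operation."""


class DataQualityError(PlanshareError):
    """A claims field carries an impossible value (e.g. negative cost share)."""


class ConvergenceError(PlanshareError):
    """An iterative fit failed to converge (separation, non-PSD information, ...)."""
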