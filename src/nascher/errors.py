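"""Exception hierarchy for cohort validation, scoring, and analysis."""


class NascherError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NascherError):
    """A table is missing a required column or has an unparseable field."""


class CohortValidationError(NascherError):
    """A cohort violates a structural invariant (referential integrity,
    date ordering, out-of-range values)."""


class UnknownItemError(NascherError):
    """An endorsed item name does not exist in the score configuration."""


class DegenerateDistributionError(NascherError):
    """A score distribution cannot be stratified into three non-empty
    categories (e.g. all scores identical)."""


class CalibrationError(NascherError):
    """The generator calibration search failed to bracket a target."""


class ConvergenceError(NascherError):
    """A model fit failed to converge (e.g. monotone Cox partial
    likelihood under covariate separation)."""
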