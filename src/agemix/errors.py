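"""Exception and warning hierarchy for agemix."""


class AgemixError(Exception):
    """Base class for all agemix errors."""


class SchemaError(AgemixError):
    """Input table is missing mandatory columns or is otherwise malformed."""


class RowParseError(AgemixError):
    """One or more data rows could not be parsed.

    Attributes
    ----------
    rows : list of int
        Zero-based indices of the offending data rows.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class ParameterError(AgemixError):
    """Density or fit parameters violate their domain constraints."""


class DegenerateDataError(AgemixError):
    """Data carry no usable signal (zero variance, empty stratum, ...)."""


class DegenerateFitError(AgemixError):
    """Every optimization start collapsed; no usable fit exists."""


class SamplingError(AgemixError):
    """Sampling cannot proceed (e.g. truncation region with negligible mass)."""


class CohortSpecError(AgemixError):
    """Synthetic-cohort specification is internally inconsistent."""


class AgemixWarning(UserWarning):
    """Base warning category for agemix."""


class AgeRangeWarning(AgemixWarning):
    """Ages fall outside the expected ascertainment window."""


class ConvergenceWarning(AgemixWarning):
    """An optimizer finished without meeting its convergence criterion."""


class TieWarning(AgemixWarning):
    """Heavy ties forced an arbitrary (stable-order) assignment."""


class ModeWarning(AgemixWarning):
    """Mode reporting fell back to component modes (merged peaks) or a
    tie-break between equal component modes."""
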