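"""Exception hierarchy for the audit pipeline.

Every stage raises a subclass of :class:`AuditError` so callers can trap
pipeline failures without catching programming errors.
"""


class AuditError(Exception):
    """Base class for all riskaudit failures."""


class SpecError(AuditError):
    """A feature specification violates its invariants."""


class CalibrationError(AuditError):
    """Intercept calibration failed to converge."""


class CohortParseError(AuditError):
    """A raw cohort cell could not be interpreted."""

    def __init__(self, row: int, column: str, token: str):
        self.row = row
        self.column = column
        self.token = token
        super().__init__(
            f"cannot parse token {token!r} in column {column!r}, row {row}"
        )


class ImputationError(AuditError):
    """A feature could not be imputed (e.g. entirely missing in training rows)."""


class SplitError(AuditError):
    """Stratified splitting is impossible (an outcome class is too small)."""


class DegenerateFeatureError(AuditError):
    """A feature has zero variance where variance is required."""


class UndefinedAUCError(AuditError):
    """AUC requested with only one outcome class present."""


class DegenerateGridError(AuditError):
    """A partial-dependence grid collapsed to a single point."""


class ConstantInputError(AuditError):
    """Rank correlation requested on a constant vector."""


class AlignmentError(AuditError):
    """Feature sets of two audit artifacts do not align."""

    def __init__(self, feature: str, where: str):
        self.feature = feature
        super().__init__(f"feature {feature!r} missing from {where}")


class InsufficientCohortError(AuditError):
    """Too few patients for the requested operation."""
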