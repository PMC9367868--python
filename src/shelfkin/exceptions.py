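"""Exception hierarchy for shelfkin.

All package errors derive from :class:`ShelfkinError` so callers can catch
everything the library raises with a single except clause.
"""


class ShelfkinError(Exception):
    """Base class for all shelfkin errors."""


class ParameterError(ShelfkinError, ValueError):
    """A kinetic parameter is outside its admissible domain."""


class NoGrowthError(ShelfkinError):
    """The observed series shows no identifiable growth to fit."""


class FittingError(ShelfkinError):
    """Nonlinear least squares failed to converge.

    Carries the best incumbent parameter vector (if any) in ``incumbent``.
    """

    def __init__(self, message, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


class DegenerateSeriesError(ShelfkinError):
    """A response series is flat or does not span the sigmoid."""


class DesignError(ShelfkinError):
    """The experimental design is rank-deficient or too small."""


class CalibrationError(ShelfkinError):
    """Color calibration bounds are invalid (ab_max <= ab_min)."""


class UnreachableThresholdError(ShelfkinError):
    """The requested microbial threshold exceeds the carrying capacity."""


class ProfileError(ShelfkinError):
    """A temperature profile is empty, non-contiguous or out of range."""


class FeasibilityError(ShelfkinError):
    """A requested effective temperature cannot be met by the profile."""


class TableFormatError(ShelfkinError):
    """A delimited input table does not match the expected schema."""


class IntegrationError(ShelfkinError):
    """The ODE solver failed on a dynamic-temperature prediction."""
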