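"""Exception hierarchy for rumenadapt."""


class RumenAdaptError(Exception):
    """Base class for all rumenadapt errors."""


class ValidationError(RumenAdaptError):
    """Raised when input records violate the measurement contract."""


class ScheduleError(RumenAdaptError):
    """Raised for inconsistent or incomplete sampling schedules."""


class InsufficientDataError(RumenAdaptError):
    """Raised when too few points are available for a fit."""


class SingularFitError(RumenAdaptError):
    """Raised when a least-squares design matrix is rank deficient."""


class InfeasibleParametersError(RumenAdaptError):
    """Raised when (v0, A, R) admit no concave quadratic with an interior peak."""


class DesignError(RumenAdaptError):
    """Raised when the experimental design cannot identify the model."""


class ParameterError(RumenAdaptError):
    """Raised for invalid user-supplied parameter values."""
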