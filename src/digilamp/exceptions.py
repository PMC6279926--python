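"""Exception and warning types shared across the package."""


class DigiLampError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(DigiLampError):
    """An assay/genome/event/tissue specification violates its contract."""


class InfeasibleDilutionError(DigiLampError):
    """Requested mean occupancy exceeds what the undiluted stock can supply."""


class EmptyPlateError(DigiLampError):
    """A plate summary was requested for zero partitions."""


class SaturationError(DigiLampError):
    """All partitions positive: the occupancy estimate is unbounded above.

    Carries ``lambda_min``, a censored lower bound derived from the lower
    confidence limit of the positive fraction.
    """

    def __init__(self, message: str, lambda_min: float | None = None):
        super().__init__(message)
        self.lambda_min = lambda_min


class InsufficientDataError(DigiLampError):
    """Too few distinct calibration levels to fit a standard curve."""


class SingularFitError(DigiLampError):
    """Standard-curve regressor has zero variance in log10(copies)."""


class TableFormatError(DigiLampError):
    """A plate or trace table is malformed (missing columns, duplicate ids)."""


class ConfigError(DigiLampError):
    """A run configuration references unknown specs or cannot be parsed."""


class ContaminationWarning(UserWarning):
    """No-template-control positives exceeded the configured tolerance."""
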