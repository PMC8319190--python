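"""Exception hierarchy shared across the package."""


class IVDDSError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(IVDDSError, ValueError):
    """A scalar parameter violates its physical constraints."""


class ValidationError(IVDDSError, ValueError):
    """A parameter bundle failed validation; message lists offending fields."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("parameter validation failed: " + "; ".join(self.problems))


class CalibrationError(IVDDSError, ValueError):
    """Fluorescence calibration values are unusable (e.g. Fl_m <= Fl_b)."""


class NoReleaseError(IVDDSError, ValueError):
    """A release trace shows no positive release slope; t_rel is undefined."""


class EstimationError(IVDDSError, RuntimeError):
    """A fitting routine failed or the data are uninformative."""


class IntegrationError(IVDDSError, RuntimeError):
    """The ODE solver did not converge."""


class ConfigurationError(IVDDSError, ValueError):
    """A config file or analysis setup is incomplete or malformed."""


class InputError(IVDDSError, ValueError):
    """Time-series inputs are empty, non-overlapping, or malformed."""
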