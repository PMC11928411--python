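"""Exception hierarchy shared across the package.

All domain errors derive from :class:`RenalSmiError` so callers can catch one
base class; validation errors always name the offending field.
"""


class RenalSmiError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RenalSmiError, ValueError):
    """A specification or input violates a documented invariant.

    The message names the offending field/value.
    """


class FormatError(RenalSmiError, ValueError):
    """A file or array does not conform to the expected format/shape."""


class DegenerateInputError(RenalSmiError, ValueError):
    """Input is structurally valid but the quantity is undefined on it
    (empty ROI, zero tissue area, zero variance, a_max = 0, ...)."""


class NoPulsatilityError(RenalSmiError, ValueError):
    """No cardiac-band pulsatility could be located in a time series."""


class NoBolusError(RenalSmiError, ValueError):
    """No contrast-bolus onset was found in a time-intensity curve."""


class FitFailureError(RenalSmiError, RuntimeError):
    """A model fit did not converge; carries the residual norm if known."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class PipelineError(RenalSmiError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
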