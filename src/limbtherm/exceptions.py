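"""Exception hierarchy.

Validation problems (bad parameters, malformed files) and numerical
failures (non-decaying data, non-positive-definite covariances) are kept
on separate branches so the CLI can map them to distinct exit codes.
"""


class LimbthermError(Exception):
    """Base class for all package errors."""


class ValidationError(LimbthermError, ValueError):
    """Invalid parameters, configuration or file contents."""


class TraceFormatError(ValidationError):
    """A temperature-trace CSV does not conform to the expected dialect."""


class ModelFormatError(ValidationError):
    """A serialized GP model file is corrupt or has an unknown schema."""


class NumericsError(LimbthermError, RuntimeError):
    """A numerical procedure failed (factorization, optimisation)."""


class NotSteadyError(NumericsError):
    """The tail of a trace is still drifting beyond tolerance."""

    def __init__(self, channel: str, slope_c_per_min: float, tol: float):
        self.channel = channel
        self.slope_c_per_min = slope_c_per_min
        super().__init__(
            f"channel {channel!r} has not reached steady state: tail slope "
            f"{slope_c_per_min:.4g} degC/min exceeds tolerance {tol:.4g}"
        )


class InsufficientDataError(NumericsError):
    """Too few usable samples remain after windowing."""


class EstimationError(NumericsError):
    """The time-constant regression is ill-posed (e.g. non-decaying data)."""
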