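"""First-order lumped-capacitance model of prosthetic layers.

A liner or socket layer sitting on a constant-temperature heat source
behaves, to a good approximation, as a single thermal capacitance
charging through a single resistance: the temperature difference to its
own steady state decays exponentially,

    T(t) = T_ss + (T_init - T_ss) * exp(-t / tau),

where ``tau = rho * c_p * V / (h * A_s)`` is the thermal time constant —
the time to traverse 63.2% (1 - 1/e) of the total step.  In the bench
experiments the material's observed asymptote sits *below* the heat-tape
set-point (contact and edge losses), so the response is parameterised by
its own steady state ``T_ss`` rather than by the source temperature.

This module provides the analytic response, forward simulation of the
single-layer and stacked-layer bench tests (heat tape at 30–40 degC,
materials at ambient 22 degC), and the library of measured materials.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "LayerKind",
    "Material",
    "FirstOrderParams",
    "TemperatureTrace",
    "StackSpec",
    "first_order_response",
    "cascaded_response",
    "simulate_single_layer",
    "simulate_stack",
]

#: Fraction of the step completed after one time constant: 1 - 1/e.
STEP_FRACTION_AT_TAU = 1.0 - np.exp(-1.0)

#: Default linear loss coefficient: the observed steady state falls below
#: the heat-source set-point by this fraction of (set-point - ambient).
DEFAULT_LOSS_COEFF = 0.15

#: Additional attenuation of the outer (socket) interface in a stack:
#: its steady-state excess over ambient relative to the liner interface's.
DEFAULT_OUTER_ATTENUATION = 0.85

_UNIFORM_RTOL = 1e-9


class LayerKind(str, enum.Enum):
    LINER = "liner"
    SOCKET = "socket"
    SOCK = "sock"


@dataclass(frozen=True)
class Material:
    """A prosthetic layer with its measured thermal time constant."""

    name: str
    kind: LayerKind
    thickness_mm: float
    tau_min: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValidationError(f"{self.name}: thickness_mm must be > 0")
        if self.tau_min <= 0:
            raise ValidationError(f"{self.name}: tau_min must be > 0")


@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of a single exponential relaxation.

    ``T_ss`` is the asymptote of the responding surface itself (not the
    heat-source temperature); ``tau_min`` is in minutes.
    """

    T_init: float
    T_ss: float
    tau_min: float

    def __post_init__(self) -> None:
        if not self.tau_min > 0:
            raise ValidationError("tau_min must be > 0")

    @property
    def tau_s(self) -> float:
        return self.tau_min * 60.0


@dataclass
class TemperatureTrace:
    """Uniformly sampled multi-channel temperature time series.

    ``channels`` maps channel name (T1/T0 for single-layer tests,
    T1/T2/T3 for stacks, skin_*/liner_* for trials) to a degC vector
    aligned with ``time_s``.
    """

    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ValidationError("time_s must be a 1-D vector of >= 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValidationError("time_s must be strictly increasing")
        step = dt[0]
        if np.any(np.abs(dt - step) > _UNIFORM_RTOL * max(abs(step), 1.0)):
            raise ValidationError("time_s spacing is not uniform")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vec in self.channels.items():
            if vec.shape != self.time_s.shape:
                raise ValidationError(
                    f"channel {name!r} has length {vec.size}, expected {self.time_s.size}"
                )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ValidationError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class StackSpec:
    """A liner + socket combination, optionally with its measured joint tau.

    ``combo_tau_min`` is the time constant observed at the liner-socket
    interface when the two layers are tested stacked; it is slower than
    either layer alone.
    """

    liner: Material
    socket: Material
    combo_tau_min: float | None = None

    def __post_init__(self) -> None:
        if self.liner.kind is not LayerKind.LINER:
            raise ValidationError(f"{self.liner.name} is not a liner")
        if self.socket.kind is not LayerKind.SOCKET:
            raise ValidationError(f"{self.socket.name} is not a socket")
        if self.combo_tau_min is not None and not self.combo_tau_min > 0:
            raise ValidationError("combo_tau_min must be > 0 when present")

    @property
    def name(self) -> str:
        return f"{self.liner.name} + {self.socket.name}"


def first_order_response(params: FirstOrderParams, time_s: np.ndarray) -> np.ndarray:
    """Evaluate T(t) = T_ss + (T_init - T_ss) exp(-t/tau) at the given times.

    Monotone from ``T_init`` toward ``T_ss``; times are in seconds and
    must be non-negative.
    """
    t = np.asarray(time_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    return params.T_ss + (params.T_init - params.T_ss) * np.exp(-t / params.tau_s)


def cascaded_response(
    T_init: float, T_ss: float, tau1_s: float, tau2_s: float, time_s: np.ndarray
) -> np.ndarray:
    """Step response of two first-order lags in series (unit DC gain).

    The normalised shape is 1 - (tau1 e^{-t/tau1} - tau2 e^{-t/tau2})/(tau1 - tau2),
    reducing to 1 - (1 + t/tau) e^{-t/tau} for equal time constants.  It
    lies below the single-lag response of either stage at every time,
    which is what makes the outer socket surface lag the liner interface.
    """
    t = np.asarray(time_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    if tau1_s <= 0 or tau2_s <= 0:
        raise ValidationError("time constants must be > 0")
    if abs(tau1_s - tau2_s) < 1e-9 * tau1_s:
        g = 1.0 - (1.0 + t / tau1_s) * np.exp(-t / tau1_s)
    else:
        g = 1.0 - (
            tau1_s * np.exp(-t / tau1_s) - tau2_s * np.exp(-t / tau2_s)
        ) / (tau1_s - tau2_s)
    return T_init + (T_ss - T_init) * g


def _time_grid(duration_s: float, sample_rate_hz: float) -> np.ndarray:
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValidationError("duration_s and sample_rate_hz must be > 0")
    n = int(np.floor(duration_s * sample_rate_hz))
    if n < 2:
        raise ValidationError("duration too short for the requested sample rate")
    return np.arange(n) / sample_rate_hz


def steady_state_below_setpoint(
    setpoint_c: float, ambient_c: float, loss_coeff: float = DEFAULT_LOSS_COEFF
) -> float:
    """Asymptote of a material surface under a heat source at ``setpoint_c``.

    The bench tests show the material plateaus below the tape set-point,
    with the deficit growing with the set-point; modelled as a linear
    loss: T_ss = setpoint - loss_coeff * (setpoint - ambient).
    """
    return setpoint_c - loss_coeff * (setpoint_c - ambient_c)


def simulate_single_layer(
    material: Material,
    setpoint_c: float,
    ambient_c: float,
    duration_s: float,
    sample_rate_hz: float = 0.5,
    noise_sd_c: float = 0.05,
    seed: int | None = None,
    loss_coeff: float = DEFAULT_LOSS_COEFF,
) -> TemperatureTrace:
    """Simulate the single-layer bench test (heat tape + one material).

    Returns a trace with channels ``T1`` (heat tape, constant and
    noiseless at the set-point) and ``T0`` (outer material surface,
    first-order rise from ambient toward a steady state strictly below
    the set-point, plus i.i.d. Gaussian measurement noise).
    """
    if setpoint_c <= ambient_c:
        raise ValidationError("setpoint_c must exceed ambient_c")
    t = _time_grid(duration_s, sample_rate_hz)
    tau_s = material.tau_min * 60.0
    metadata: dict = {"material": material.name, "setpoint_c": setpoint_c,
                      "ambient_c": ambient_c, "seed": seed}
    if duration_s < tau_s:
        metadata["short_duration"] = True
    if duration_s < 5 * tau_s:
        warnings.warn(
            f"duration {duration_s:.0f} s covers less than 5 tau "
            f"({5 * tau_s:.0f} s) for {material.name}",
            stacklevel=2,
        )
    T_ss = steady_state_below_setpoint(setpoint_c, ambient_c, loss_coeff)
    T0 = first_order_response(
        FirstOrderParams(T_init=ambient_c, T_ss=T_ss, tau_min=material.tau_min), t
    )
    if noise_sd_c > 0:
        rng = np.random.default_rng(seed)
        T0 = T0 + rng.normal(0.0, noise_sd_c, t.size)
    T1 = np.full_like(t, setpoint_c)
    return TemperatureTrace(t, {"T1": T1, "T0": T0}, sample_rate_hz, metadata)


def simulate_stack(
    stack: StackSpec,
    setpoint_c: float,
    ambient_c: float,
    duration_s: float,
    sample_rate_hz: float = 0.5,
    noise_sd_c: float = 0.05,
    seed: int | None = None,
    loss_coeff: float = DEFAULT_LOSS_COEFF,
    outer_attenuation: float = DEFAULT_OUTER_ATTENUATION,
) -> TemperatureTrace:
    """Simulate the stacked bench test (heat tape + liner + socket).

    Channels: ``T1`` heat tape (constant), ``T2`` liner-socket interface
    (first-order with the measured combination tau), ``T3`` outer socket
    surface (second cascaded node, lagging T2 with the socket's own tau
    and a lower asymptote).  Noiseless ordering T3 <= T2 <= T1 holds at
    every sample.
    """
    if stack.combo_tau_min is None:
        raise ValidationError(
            f"stack {stack.name!r} has no combo_tau_min; the liner-interface "
            "time constant is required for simulation"
        )
    if setpoint_c <= ambient_c:
        raise ValidationError("setpoint_c must exceed ambient_c")
    t = _time_grid(duration_s, sample_rate_hz)
    tau2_s = stack.combo_tau_min * 60.0
    tau3_s = stack.socket.tau_min * 60.0
    metadata: dict = {"stack": stack.name, "setpoint_c": setpoint_c,
                      "ambient_c": ambient_c, "seed": seed}
    if duration_s < tau2_s:
        metadata["short_duration"] = True
    if duration_s < 5 * tau2_s:
        warnings.warn(
            f"duration {duration_s:.0f} s covers less than 5 tau "
            f"({5 * tau2_s:.0f} s) for {stack.name}",
            stacklevel=2,
        )
    T2_ss = steady_state_below_setpoint(setpoint_c, ambient_c, loss_coeff)
    T3_ss = ambient_c + outer_attenuation * (T2_ss - ambient_c)
    T2 = first_order_response(
        FirstOrderParams(T_init=ambient_c, T_ss=T2_ss, tau_min=stack.combo_tau_min), t
    )
    T3 = cascaded_response(ambient_c, T3_ss, tau2_s, tau3_s, t)
    if noise_sd_c > 0:
        rng = np.random.default_rng(seed)
        T2 = T2 + rng.normal(0.0, noise_sd_c, t.size)
        T3 = T3 + rng.normal(0.0, noise_sd_c, t.size)
    T1 = np.full_like(t, setpoint_c)
    return TemperatureTrace(t, {"T1": T1, "T2": T2, "T3": T3}, sample_rate_hz, metadata)
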