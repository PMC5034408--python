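"""Thermal time constant estimation by the logarithmic method.

A first-order heating curve satisfies ``T_ss - T(t) = (T_ss - T(0)) e^{-t/tau}``,
so the log of the steady-state deficit is linear in time with slope
``-1/tau``.  The estimator therefore (1) detects the steady state from
the trace tail, (2) forms ``ln(T_ss - T(t))`` over a fit window, and
(3) runs ordinary least squares, reporting ``tau = -1/slope``.

Two refinements make the method robust on real (finite, noisy)
recordings, where the raw tail mean understates the true asymptote and
log-transformed noise near steady state is badly skewed:

* the fit window is the contiguous prefix of samples whose deficit
  exceeds both ``min_delta_c`` and a fraction (default 5%) of the
  detected step, dropping the first sample (donning/contact transient);
* the steady-state value may be refined (default on) by maximising the
  R² of the log-linear fit over ``T_ss`` at or above the tail mean —
  for noiseless truncated data this recovers the exact asymptote, since
  only the true ``T_ss`` makes the log-deficit exactly linear.

For stacked-layer traces the channel must be the liner interface
(``T2``) and the steady state its own asymptote ``T_2ss``, not the
outer socket surface's — the predictive model consumes liner
temperature, so the liner-interface time constant is the one of
interest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    EstimationError,
    InsufficientDataError,
    NotSteadyError,
    ValidationError,
)
from .thermal import TemperatureTrace

__all__ = [
    "TauEstimate",
    "TauAggregate",
    "detect_steady_state",
    "log_linearize",
    "estimate_tau",
    "aggregate_tau",
]


@dataclass(frozen=True)
class TauEstimate:
    """Result of one logarithmic-method fit."""

    tau_min: float
    slope_per_s: float
    intercept: float
    r_squared: float
    n_points_used: int
    steady_state_c: float
    fit_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.tau_min > 0:
            raise ValidationError("tau_min must be > 0")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.n_points_used < 3:
            raise ValidationError("a fit needs at least 3 points")


@dataclass(frozen=True)
class TauAggregate:
    """Time constant pooled across heat-source set-points."""

    tau_mean_min: float
    tau_per_setpoint: dict[float, float]
    dispersion_min: float


def detect_steady_state(
    trace: TemperatureTrace,
    channel: str,
    tail_fraction: float = 0.1,
    slope_tol_c_per_min: float = 0.05,
) -> float:
    """Mean of the trace tail, guarded by a residual-slope check.

    Averages the final ``tail_fraction`` of samples and verifies, by a
    straight-line fit over that tail, that the channel is no longer
    drifting faster than ``slope_tol_c_per_min``; otherwise raises
    :class:`NotSteadyError` naming the channel and observed slope.
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ValidationError("tail_fraction must be in (0, 1]")
    y = trace.channel(channel)
    k = max(int(np.ceil(y.size * tail_fraction)), 3)
    t_tail = trace.time_s[-k:] / 60.0  # minutes, for the slope units
    y_tail = y[-k:]
    slope = float(np.polyfit(t_tail, y_tail, 1)[0]) if np.ptp(y_tail) > 0 else 0.0
    if abs(slope) > slope_tol_c_per_min:
        raise NotSteadyError(channel, slope, slope_tol_c_per_min)
    return float(y_tail.mean())


def log_linearize(
    trace: TemperatureTrace,
    channel: str,
    steady_state_c: float,
    min_delta_c: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(t, ln(T_ss - T(t)))`` for samples still short of steady state.

    Samples whose deficit ``T_ss - T(t)`` is below ``min_delta_c`` are
    excluded (the log would amplify noise, or be undefined at or above
    the asymptote); order is preserved.  Raises
    :class:`InsufficientDataError` if fewer than 3 samples survive.
    """
    if not np.isfinite(steady_state_c):
        raise ValidationError("steady_state_c must be finite")
    y = trace.channel(channel)
    delta = steady_state_c - y
    keep = delta >= min_delta_c
    if int(keep.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} samples lie more than {min_delta_c} degC "
            f"below the steady state on channel {channel!r}"
        )
    return trace.time_s[keep], np.log(delta[keep])


def _ols_window(
    time_s: np.ndarray,
    y: np.ndarray,
    steady_state_c: float,
    min_delta_c: float,
    amp_fraction: float,
    drop_first: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit window + OLS in log space; returns (slope, intercept, r2) inputs."""
    delta = steady_state_c - y
    threshold = min_delta_c
    if delta[0] > 0:
        threshold = max(threshold, amp_fraction * delta[0])
    below = delta < threshold
    end = int(np.argmax(below)) if below.any() else delta.size
    start = 1 if drop_first else 0
    return time_s[start:end], delta[start:end], threshold


def _log_ols(t: np.ndarray, delta: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, np.log(delta))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def estimate_tau(
    trace: TemperatureTrace,
    channel: str,
    *,
    steady_state_c: float | None = None,
    tail_fraction: float = 0.1,
    slope_tol_c_per_min: float = 0.05,
    min_delta_c: float = 0.1,
    amp_fraction: float = 0.05,
    drop_first: bool = True,
    refine_steady_state: bool = True,
) -> TauEstimate:
    """Estimate the thermal time constant of one channel.

    Runs steady-state detection (unless ``steady_state_c`` is given),
    optional R²-maximising refinement of the asymptote, and ordinary
    least squares on the log-deficit; ``tau = -1/slope``, reported in
    minutes.  For stacked traces pass ``channel='T2'`` (liner
    interface).  Raises :class:`EstimationError` if the windowed data do
    not decay.
    """
    y = trace.channel(channel)
    if steady_state_c is None:
        ss = detect_steady_state(trace, channel, tail_fraction, slope_tol_c_per_min)
    else:
        ss = float(steady_state_c)

    def window(ss_value: float):
        t_w, d_w, thr = _ols_window(
            trace.time_s, y, ss_value, min_delta_c, amp_fraction, drop_first
        )
        if t_w.size < 3 or np.any(d_w <= 0):
            return None
        return t_w, d_w

    if refine_steady_state and steady_state_c is None:
        span = float(np.ptp(y))

        def neg_r2(ss_value: float) -> float:
            w = window(ss_value)
            if w is None:
                return 1.0
            return -_log_ols(*w)[2]

        res = optimize.minimize_scalar(
            neg_r2,
            bounds=(ss, ss + 0.5 * max(span, 1e-6)),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if res.success and -res.fun >= -neg_r2(ss):
            ss = float(res.x)

    w = window(ss)
    if w is None:
        raise InsufficientDataError(
            f"fewer than 3 usable samples below the steady state on {channel!r}"
        )
    t_w, d_w = w
    slope, intercept, r2 = _log_ols(t_w, d_w)
    if slope >= 0:
        raise EstimationError(
            f"log-deficit on channel {channel!r} is not decaying "
            f"(slope {slope:.3g} 1/s >= 0)"
        )
    return TauEstimate(
        tau_min=-1.0 / slope / 60.0,
        slope_per_s=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points_used=int(t_w.size),
        steady_state_c=ss,
        fit_window_s=(float(t_w[0]), float(t_w[-1])),
    )


def aggregate_tau(estimates: dict[float, TauEstimate]) -> TauAggregate:
    """Pool per-set-point estimates into a mean tau with sample dispersion.

    Repeating the bench test at set-points 30–40 degC and averaging
    confirms the estimate: the time constant is a material property and
    should not depend on the source temperature.  Warns when the
    relative dispersion exceeds 10%.
    """
    if not estimates:
        raise ValidationError("no estimates to aggregate")
    if len(estimates) < 2:
        raise ValidationError("aggregation needs at least 2 set-points")
    taus = np.array([e.tau_min for e in estimates.values()], dtype=float)
    mean = float(taus.mean())
    sd = float(taus.std(ddof=1))
    if mean > 0 and sd / mean > 0.1:
        warnings.warn(
            f"per-set-point time constants disperse by {sd / mean:.1%} of the "
            "mean; check the recordings",
            stacklevel=2,
        )
    return TauAggregate(
        tau_mean_min=mean,
        tau_per_setpoint={float(k): float(v.tau_min) for k, v in estimates.items()},
        dispersion_min=sd,
    )
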