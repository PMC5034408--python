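"""Synthetic amputee-trial generator.

Emulates the 35-minute climate-chamber protocol used to collect paired
skin/liner recordings: donning/rest for 10 min, treadmill walking for
10 min, final rest for 15 min, four thermocouples (skin and liner, each
at a lateral and a medial site) sampled at 0.5 Hz at a controlled
ambient temperature.

The skin model is deliberately simple, first-order piecewise kinetics:
within each phase the skin relaxes exponentially (physiological time
constant, default 8 min) toward a phase equilibrium — the resting
equilibrium rises weakly with ambient temperature, and walking raises
it by a fixed activity gain (default 1.5 degC).  The liner-socket
interface is a first-order lag of the skin with the *stack's* measured
thermal time constant, attenuated toward ambient (the interface sits
part-way between skin and surroundings).  I.i.d. Gaussian measurement
noise is added to every channel.  The noise-free channels and every
generator parameter are kept on the recording, so model accuracy can be
scored against ground truth.

What this generator does not emulate: perspiration and evaporative
cooling, gait-cycle micro-oscillations, sensor drift, and
subject-specific physiology.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import ValidationError
from .thermal import StackSpec, TemperatureTrace

__all__ = [
    "TrialProtocol",
    "PhysioParams",
    "TrialRecording",
    "generate_trial",
    "time_average",
]


@dataclass(frozen=True)
class TrialProtocol:
    """Rest/walk/rest protocol of one recording session."""

    rest1_min: float = 10.0
    walk_min: float = 10.0
    rest2_min: float = 15.0
    sample_rate_hz: float = 0.5
    ambient_c: float = 20.0
    humidity_pct: float = 40.0  # metadata only

    def __post_init__(self) -> None:
        if min(self.rest1_min, self.walk_min, self.rest2_min) <= 0:
            raise ValidationError("phase durations must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")

    @property
    def total_min(self) -> float:
        return self.rest1_min + self.walk_min + self.rest2_min


@dataclass(frozen=True)
class PhysioParams:
    """Tunable physiological constants of the synthetic subject.

    The resting skin equilibrium is
    ``rest_equilibrium_base_c + rest_equilibrium_per_ambient * ambient``
    so that skin sits in the observed 30–34 degC band across chamber
    settings of 10–25 degC.  ``liner_coupling`` is the fraction of the
    skin excess over ambient that the liner-socket interface tracks.
    """

    rest_equilibrium_base_c: float = 30.5
    rest_equilibrium_per_ambient: float = 0.06
    donning_offset_c: float = -0.3
    activity_gain_c: float = 1.5
    phase_tau_min: float = 8.0
    liner_coupling: float = 0.6
    lateral_medial_offset_c: float = 0.3
    noise_sd_c: float = 0.1

    def __post_init__(self) -> None:
        if self.phase_tau_min <= 0:
            raise ValidationError("phase_tau_min must be > 0")
        if not (0.0 < self.liner_coupling <= 1.0):
            raise ValidationError("liner_coupling must be in (0, 1]")
        if self.noise_sd_c < 0:
            raise ValidationError("noise_sd_c must be >= 0")


@dataclass
class TrialRecording:
    """Paired skin/liner traces plus protocol and full generator truth."""

    trace: TemperatureTrace
    clean_trace: TemperatureTrace
    protocol: TrialProtocol
    truth: dict


def _skin_and_liner(
    protocol: TrialProtocol, params: PhysioParams, stack_tau_min: float, ambient: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact exponential stepping of the coupled skin/liner system.

    Both ODEs are integrated with per-sample exact exponential updates
    (zero-order hold of the drive over one sample interval).
    """
    dt = 1.0 / protocol.sample_rate_hz
    n = int(round(protocol.total_min * 60.0 * protocol.sample_rate_hz))
    t = np.arange(n) * dt
    eq_rest = (
        params.rest_equilibrium_base_c + params.rest_equilibrium_per_ambient * ambient
    )
    tau_p = params.phase_tau_min * 60.0
    tau_l = stack_tau_min * 60.0
    decay_p = np.exp(-dt / tau_p)
    decay_l = np.exp(-dt / tau_l)
    t_walk_start = protocol.rest1_min * 60.0
    t_walk_end = (protocol.rest1_min + protocol.walk_min) * 60.0

    skin = np.empty(n)
    liner = np.empty(n)
    s = eq_rest + params.donning_offset_c
    l = ambient  # prosthesis starts at chamber temperature
    for i in range(n):
        skin[i] = s
        liner[i] = l
        target = eq_rest + (
            params.activity_gain_c if t_walk_start <= t[i] < t_walk_end else 0.0
        )
        s = target + (s - target) * decay_p
        drive = params.liner_coupling * s + (1.0 - params.liner_coupling) * ambient
        l = drive + (l - drive) * decay_l
    return t, skin, liner


def generate_trial(
    protocol: TrialProtocol | None = None,
    stack: StackSpec | None = None,
    params: PhysioParams | None = None,
    seed: int | None = None,
    *,
    stack_tau_min: float | None = None,
) -> TrialRecording:
    """Generate one synthetic rest/walk/rest recording.

    The stack's liner-interface time constant (from ``stack`` or given
    directly as ``stack_tau_min``) sets the liner lag.  Channels:
    ``skin_lateral``, ``skin_medial``, ``liner_lateral``,
    ``liner_medial``; the same channels without noise are on
    ``clean_trace``.  Identical seeds give bit-identical recordings.
    """
    protocol = protocol or TrialProtocol()
    params = params or PhysioParams()
    if stack_tau_min is None:
        if stack is None or stack.combo_tau_min is None:
            raise ValidationError(
                "a StackSpec with combo_tau_min (or stack_tau_min=) is required"
            )
        stack_tau_min = stack.combo_tau_min
    if stack_tau_min <= 0:
        raise ValidationError("stack_tau_min must be > 0")

    t, skin_lat, liner_lat = _skin_and_liner(
        protocol, params, stack_tau_min, protocol.ambient_c
    )
    off = params.lateral_medial_offset_c
    clean = {
        "skin_lateral": skin_lat,
        "skin_medial": skin_lat - off,
        "liner_lateral": liner_lat,
        "liner_medial": liner_lat - params.liner_coupling * off,
    }
    rng = np.random.default_rng(seed)
    noisy = {
        name: vec + rng.normal(0.0, params.noise_sd_c, vec.size)
        for name, vec in clean.items()
    }
    truth = {
        "stack_tau_min": float(stack_tau_min),
        "stack": stack.name if stack is not None else None,
        "seed": seed,
        "ambient_c": protocol.ambient_c,
        **asdict(params),
    }
    meta = {"seed": seed, "protocol": asdict(protocol)}
    return TrialRecording(
        trace=TemperatureTrace(t, noisy, protocol.sample_rate_hz, dict(meta)),
        clean_trace=TemperatureTrace(t, clean, protocol.sample_rate_hz, dict(meta)),
        protocol=protocol,
        truth=truth,
    )


def time_average(trace: TemperatureTrace, window_s: float) -> TemperatureTrace:
    """Non-overlapping block means over ``window_s`` windows.

    The block size is ``floor(window_s * sample_rate)`` samples (a 5-s
    window at 0.5 Hz averages 2 samples); the trailing partial block is
    dropped, every channel is averaged identically, and block times are
    the means of the member sample times.
    """
    dt = 1.0 / trace.sample_rate_hz
    if window_s < dt:
        raise ValidationError(
            f"window_s ({window_s} s) is smaller than the sample interval ({dt} s)"
        )
    block = int(np.floor(window_s * trace.sample_rate_hz))
    n_blocks = trace.n_samples // block
    if n_blocks < 2:
        raise ValidationError("trace too short for this averaging window")
    m = n_blocks * block

    def avg(vec: np.ndarray) -> np.ndarray:
        return vec[:m].reshape(n_blocks, block).mean(axis=1)

    return TemperatureTrace(
        avg(trace.time_s),
        {name: avg(vec) for name, vec in trace.channels.items()},
        trace.sample_rate_hz / block,
        {**trace.metadata, "time_average_window_s": window_s},
    )
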