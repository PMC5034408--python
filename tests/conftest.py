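import numpy as np
import pytest

from limbtherm import (
    FirstOrderParams,
    TemperatureTrace,
    first_order_response,
    material_library,
)


@pytest.fixture(scope="session")
def library():
    return material_library()


@pytest.fixture(scope="session")
def technogel_stack(library):
    return library.stack("OttoBock Technogel", "thermosetting lay-up")


@pytest.fixture(scope="session")
def pelite_stack(library):
    return library.stack("Pe-lite", "thermoplastic")


def make_exponential_trace(
    tau_min: float,
    T_init: float = 22.0,
    T_ss: float = 34.0,
    duration_min: float | None = None,
    rate_hz: float = 0.5,
    channel: str = "T0",
) -> TemperatureTrace:
    """Noiseless single-exponential trace, default duration 20 tau."""
    if duration_min is None:
        duration_min = 20.0 * tau_min
    t = np.arange(int(duration_min * 60 * rate_hz)) / rate_hz
    y = first_order_response(FirstOrderParams(T_init, T_ss, tau_min), t)
    return TemperatureTrace(t, {channel: y}, rate_hz)
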