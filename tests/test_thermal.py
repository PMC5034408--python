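"""First-order response, bench simulations and the material library."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import limbtherm as lt
from limbtherm.thermal import STEP_FRACTION_AT_TAU, steady_state_below_setpoint

PARAMS = lt.FirstOrderParams(T_init=22.0, T_ss=34.0, tau_min=2.8)


class TestFirstOrderResponse:
    def test_initial_condition(self):
        assert lt.first_order_response(PARAMS, np.array([0.0]))[0] == pytest.approx(22.0)

    def test_one_tau_reaches_632_percent_of_step(self):
        T = lt.first_order_response(PARAMS, np.array([2.8 * 60.0]))[0]
        fraction = (T - 22.0) / (34.0 - 22.0)
        assert fraction == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)
        assert fraction == pytest.approx(0.632, abs=5e-4)

    def test_long_time_asymptote(self):
        T = lt.first_order_response(PARAMS, np.array([20 * 2.8 * 60.0]))[0]
        assert T == pytest.approx(34.0, abs=1e-6)

    def test_satisfies_first_order_ode(self):
        # five-point stencil so the check is limited by the ODE, not the stencil
        tau_s = PARAMS.tau_s
        h = 0.01 * tau_s
        t0 = np.linspace(2 * h, 5 * tau_s, 40)
        stencil = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / (12.0 * h)
        offsets = np.array([-2, -1, 0, 1, 2]) * h
        T = lt.first_order_response(PARAMS, t0[:, None] + offsets[None, :])
        dTdt = T @ stencil
        delta = T[:, 2] - PARAMS.T_ss
        np.testing.assert_allclose(dTdt, -delta / tau_s, rtol=1e-6)

    def test_exact_one_step_decay_identity(self):
        t = np.linspace(0.0, 10 * PARAMS.tau_s, 500)
        T = lt.first_order_response(PARAMS, t)
        dt = t[1] - t[0]
        np.testing.assert_allclose(
            T[1:] - PARAMS.T_ss, (T[:-1] - PARAMS.T_ss) * np.exp(-dt / PARAMS.tau_s),
            rtol=1e-10, atol=1e-13,
        )

    def test_negative_time_rejected(self):
        with pytest.raises(lt.ValidationError):
            lt.first_order_response(PARAMS, np.array([-1.0]))

    def test_non_positive_tau_rejected(self):
        with pytest.raises(lt.ValidationError):
            lt.FirstOrderParams(22.0, 34.0, 0.0)

    @given(
        T_init=st.floats(0.0, 40.0),
        T_ss=st.floats(0.0, 40.0),
        tau_min=st.floats(0.1, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_toward_steady_state(self, T_init, T_ss, tau_min):
        t = np.linspace(0.0, 10 * tau_min * 60, 200)
        T = lt.first_order_response(lt.FirstOrderParams(T_init, T_ss, tau_min), t)
        dT = np.diff(T)
        if T_init < T_ss:
            assert np.all(dT >= 0)
        else:
            assert np.all(dT <= 0)
        assert np.all(np.abs(T - T_ss) <= abs(T_init - T_ss) + 1e-12)


class TestSimulateSingleLayer:
    def test_noiseless_round_trip_recovers_tau(self, library):
        mat = library.material("OttoBock Technogel")
        trace = lt.simulate_single_layer(mat, 30.0, 22.0, 3600.0, 0.5, 0.0, seed=1)
        est = lt.estimate_tau(trace, "T0")
        assert est.tau_min == pytest.approx(2.8, abs=1e-6)

    def test_material_plateaus_below_heat_source(self, library):
        mat = library.material("Pe-lite")
        trace = lt.simulate_single_layer(mat, 34.0, 22.0, 3600.0, 0.5, 0.0, seed=1)
        assert trace.channel("T0").max() < 34.0
        assert np.all(trace.channel("T1") == 34.0)

    def test_same_seed_identical(self, library):
        mat = library.material("Iceross Comfort")
        kw = dict(setpoint_c=34.0, ambient_c=22.0, duration_s=3600.0,
                  sample_rate_hz=0.5, noise_sd_c=0.05, seed=7)
        a = lt.simulate_single_layer(mat, **kw)
        b = lt.simulate_single_layer(mat, **kw)
        assert np.array_equal(a.channel("T0"), b.channel("T0"))

    def test_short_duration_flagged(self, library):
        mat = library.material("carbon fibre lay-up")  # tau 4.5 min
        with pytest.warns(UserWarning, match="5 tau"):
            trace = lt.simulate_single_layer(mat, 34.0, 22.0, 120.0, 0.5, 0.0, seed=1)
        assert trace.metadata.get("short_duration") is True

    def test_setpoint_not_above_ambient_rejected(self, library):
        mat = library.material("Pe-lite")
        with pytest.raises(lt.ValidationError):
            lt.simulate_single_layer(mat, 20.0, 22.0, 3600.0, 0.5, 0.0, seed=1)


class TestSimulateStack:
    def test_outward_temperature_ordering(self, technogel_stack):
        trace = lt.simulate_stack(technogel_stack, 34.0, 22.0, 5400.0, 0.5, 0.0, seed=1)
        T1, T2, T3 = (trace.channel(c) for c in ("T1", "T2", "T3"))
        assert np.all(T3 <= T2 + 1e-12)
        assert np.all(T2 <= T1 + 1e-12)

    def test_liner_interface_recovers_combo_tau(self, technogel_stack):
        trace = lt.simulate_stack(technogel_stack, 34.0, 22.0, 6500.0, 0.5, 0.0, seed=1)
        est = lt.estimate_tau(trace, "T2")
        assert est.tau_min == pytest.approx(5.4, abs=1e-6)

    def test_combination_slower_than_individual_liner(self, technogel_stack):
        # same set-up, same asymptote: the stacked liner interface must heat
        # more slowly than the liner alone at every interior time
        kw = dict(setpoint_c=34.0, ambient_c=22.0, duration_s=int(5 * 5.4 * 60),
                  sample_rate_hz=0.5, noise_sd_c=0.0, seed=1)
        single = lt.simulate_single_layer(technogel_stack.liner, **kw)
        stacked = lt.simulate_stack(technogel_stack, **kw)
        t0 = single.channel("T0")[1:]
        t2 = stacked.channel("T2")[1:]
        assert np.all(t2 < t0)

    def test_missing_combo_tau_rejected(self, library):
        bare = lt.StackSpec(
            liner=library.material("Pe-lite"),
            socket=library.material("thermoplastic"),
        )
        with pytest.raises(lt.ValidationError, match="combo_tau_min"):
            lt.simulate_stack(bare, 34.0, 22.0, 3600.0, 0.5, 0.0, seed=1)


class TestMaterialLibrary:
    @pytest.mark.parametrize(
        "name, kind, thickness, tau",
        [
            ("Alpha Locking", lt.LayerKind.LINER, 6.0, 3.6),
            ("Iceross Comfort", lt.LayerKind.LINER, 6.0, 3.1),
            ("Iceross Original", lt.LayerKind.LINER, 3.0, 2.6),
            ("OttoBock Technogel", lt.LayerKind.LINER, 6.0, 2.8),
            ("Pe-lite", lt.LayerKind.LINER, 5.0, 1.6),
            ("stump sock", lt.LayerKind.SOCK, 0.7, 0.6),
            ("thermoplastic", lt.LayerKind.SOCKET, 4.7, 4.0),
            ("thermosetting lay-up", lt.LayerKind.SOCKET, 4.0, 4.1),
            ("carbon fibre lay-up", lt.LayerKind.SOCKET, 4.8, 4.5),
        ],
    )
    def test_single_materials(self, library, name, kind, thickness, tau):
        m = library.material(name)
        assert m.kind is kind
        assert m.thickness_mm == thickness
        assert m.tau_min == tau

    @pytest.mark.parametrize(
        "liner, socket, combo_tau",
        [
            ("OttoBock Technogel", "thermosetting lay-up", 5.4),
            ("Iceross Comfort", "carbon fibre lay-up", 5.5),
            ("Iceross Original", "carbon fibre lay-up", 4.1),
            ("Iceross Comfort", "thermosetting lay-up", 5.8),
            ("Alpha Locking", "carbon fibre lay-up", 6.2),
            ("Pe-lite", "thermoplastic", 6.7),
        ],
    )
    def test_combinations(self, library, liner, socket, combo_tau):
        assert library.stack(liner, socket).combo_tau_min == combo_tau

    def test_counts(self, library):
        assert len(library.materials) == 9
        assert len(library.stacks) == 6

    def test_unknown_material_rejected(self, library):
        with pytest.raises(lt.ValidationError, match="unknown material"):
            library.material("vibranium")


def test_loss_model_keeps_steady_state_between_ambient_and_setpoint():
    for sp in (30.0, 34.0, 40.0):
        ss = steady_state_below_setpoint(sp, 22.0)
        assert 22.0 < ss < sp
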