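"""Model definitions: parameter tables, gating laws, equilibrium currents, rhs."""

import math

import numpy as np
import pytest

from rampclamp import (
    Model, equilibrium_current, gating_steady_state, get_model,
    make_leak_model, make_morris_lecar, rhs,
)
from rampclamp.errors import InputError


def _current(model, name):
    return next(c for c in model.currents if c.name == name)


class TestMorrisLecar:
    @pytest.mark.parametrize("cls,gCa,V4,phi,gc", [
        ("I", 4.0, 17.4, 0.067, 40.0),
        ("II", 4.4, 30.0, 0.040, 150.0),
    ])
    def test_class_parameters(self, cls, gCa, V4, phi, gc):
        m = make_morris_lecar(cls)
        assert m.capacitance == 20.0
        assert _current(m, "Ca").g_max == gCa
        assert _current(m, "Ca").E_rev == 120.0
        assert _current(m, "K").g_max == 12.0
        assert _current(m, "K").E_rev == -84.0
        assert _current(m, "L").g_max == 2.0
        w = _current(m, "K").gates[0]
        assert w.params[1] == V4
        assert w.rate_scale == phi
        assert m.gc_default == gc
        assert m.state_dim == 2  # (V, w); Ca activation is instantaneous

    def test_unknown_class_rejected(self):
        with pytest.raises(InputError):
            make_morris_lecar("III")

    def test_gating_half_activation_and_saturation(self, ml1):
        g = gating_steady_state(ml1, -1.2)  # V1: tanh argument vanishes
        assert g["m"] == pytest.approx(0.5)
        g_hi = gating_steady_state(ml1, 1000.0)
        assert g_hi["m"] == pytest.approx(1.0)
        assert g_hi["w"] == pytest.approx(1.0)

    def test_gating_at_rest_matches_direct_formula(self, ml1):
        # independent evaluation of the printed activation curves at V = -60
        m_exp = 0.5 * (1 + math.tanh((-60 + 1.2) / 18))
        w_exp = 0.5 * (1 + math.tanh((-60 - 12) / 17.4))
        g = gating_steady_state(ml1, -60.0)
        assert g["m"] == pytest.approx(m_exp, rel=1e-12)
        assert g["w"] == pytest.approx(w_exp, rel=1e-12)
        assert m_exp == pytest.approx(0.00145, abs=2e-5)

    def test_equilibrium_current_at_rest(self, ml1):
        # hand-evaluated sum: gL*0 + gCa*m_inf*(V-VCa) + gK*w_inf*(V-VK)
        m_exp = 0.5 * (1 + math.tanh((-60 + 1.2) / 18))
        w_exp = 0.5 * (1 + math.tanh((-60 - 12) / 17.4))
        i_exp = 4.0 * m_exp * (-60 - 120) + 12.0 * w_exp * (-60 + 84)
        assert equilibrium_current(ml1, -60.0) == pytest.approx(i_exp, rel=1e-12)
        assert i_exp == pytest.approx(-0.97, abs=0.01)

    def test_s_shape_has_exactly_two_turning_points(self, ml1):
        # dense sign scan of the numerical derivative of I_eq on [-80, 30]
        V = np.linspace(-80, 30, 20001)
        d = np.diff(equilibrium_current(ml1, V))
        assert int(np.count_nonzero(np.diff(np.sign(d)) != 0)) == 2


class TestWangBuzsaki:
    def test_table_parameters(self, wb):
        assert wb.capacitance == 1.0
        assert _current(wb, "Na").g_max == 35.0
        assert _current(wb, "Na").E_rev == 55.0
        assert _current(wb, "K").g_max == 9.0
        assert _current(wb, "K").E_rev == -90.0
        assert _current(wb, "L").g_max == pytest.approx(0.1)
        assert _current(wb, "L").E_rev == -65.0
        assert wb.gc_default == 20.0

    def test_state_dimension_is_three(self, wb):
        # m is instantaneous (enters as m_inf^3); only h and n are dynamic
        assert wb.state_dim == 3
        assert [g.name for g in wb.dynamic_gates] == ["h", "n"]
        assert _current(wb, "Na").gates[0].exponent == 3
        assert _current(wb, "K").gates[0].exponent == 4

    def test_n_steady_state_matches_rate_formulas(self, wb):
        # independent evaluation of alpha_n/(alpha_n + beta_n) at V = -65
        V = -65.0
        a = 0.01 * (V + 34) / (1 - math.exp(-0.1 * (V + 34)))
        b = 0.125 * math.exp(-0.0125 * (V + 44))
        assert gating_steady_state(wb, V)["n"] == pytest.approx(a / (a + b), rel=1e-10)

    def test_rate_singularities_are_removable(self, wb):
        # alpha_m has a 0/0 at V = -35, alpha_n at V = -34; values must interpolate
        for name, v0 in (("m", -35.0), ("n", -34.0)):
            lo = gating_steady_state(wb, v0 - 1e-4)[name]
            mid = gating_steady_state(wb, v0)[name]
            hi = gating_steady_state(wb, v0 + 1e-4)[name]
            assert np.isfinite(mid)
            assert min(lo, hi) <= mid <= max(lo, hi)


class TestLeakModel:
    def test_equilibrium_current_closed_form(self, leak):
        assert equilibrium_current(leak, -60.0) == 0.0
        assert equilibrium_current(leak, -50.0) == pytest.approx(20.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InputError):
            make_leak_model(gL=0.0)
        with pytest.raises(InputError):
            make_leak_model(C=-1.0)

    def test_rhs_is_current_over_capacitance(self, leak):
        dy = rhs(leak, np.array([-60.0]), 20.0)
        assert dy[0] == pytest.approx(1.0)  # 20 pA / 20 pF


class TestRhs:
    @pytest.mark.parametrize("name", ["morris_lecar_I", "morris_lecar_II",
                                      "wang_buzsaki", "leak"])
    def test_zero_at_equilibrium(self, name):
        model = get_model(name)
        for V in (-70.0, -40.0, 0.0):
            state = model.equilibrium_state(V)
            i_eq = float(model.equilibrium_current(V))
            assert np.allclose(rhs(model, state, i_eq), 0.0, atol=1e-12)

    def test_rest_drift_matches_equilibrium_current(self, ml1):
        state = ml1.equilibrium_state(-60.0)
        dy = rhs(ml1, state, 0.0)
        assert dy[0] == pytest.approx(-float(ml1.equilibrium_current(-60.0)) / 20.0)
        assert dy[0] == pytest.approx(0.0486, abs=5e-4)

    def test_dimension_mismatch_rejected(self, ml1):
        with pytest.raises(InputError):
            rhs(ml1, np.array([-60.0, 0.1, 0.2]), 0.0)


@pytest.mark.parametrize("name", ["morris_lecar_I", "morris_lecar_II", "wang_buzsaki"])
def test_gate_ranges_and_time_constants(name):
    """All gate steady states in [0,1] and time constants positive on [-120, 60] mV."""
    model = get_model(name)
    V = np.linspace(-120.0, 60.0, 721)
    for cur in model.currents:
        for gate in cur.gates:
            x = gate.steady_state(V)
            assert np.all((x >= 0.0) & (x <= 1.0))
            assert np.all(gate.time_constant(V) > 0.0)


@pytest.mark.parametrize("name", ["morris_lecar_I", "wang_buzsaki"])
def test_equilibrium_current_consistent_with_gates(name):
    """I_eq equals the total ionic current evaluated at the gate steady states."""
    model = get_model(name)
    for V in (-75.0, -30.0, 10.0):
        dyn = model.dynamic_gate_steady_state(V)
        assert model.ionic_current(V, dyn) == pytest.approx(
            float(model.equilibrium_current(V)), rel=1e-12)


def test_config_round_trip(ml1, wb):
    for model in (ml1, wb):
        clone = Model.from_config(model.to_config())
        V = np.linspace(-90, 40, 53)
        assert np.allclose(clone.equilibrium_current(V), model.equilibrium_current(V))
        assert clone.state_dim == model.state_dim
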