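import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from p2ca import core
from p2ca.core import (ModelState, MARKOV_STATES, er_leak_flux, full_rhs,
                       gating_functions, ip3r_flux, ip3r_open_probability,
                       p2x7_flux, p2x7_transition_matrix, pump_flux,
                       rhs_function)
from p2ca.params import ModelParameters


def make_state(**kw):
    base = dict(ca_i=0.1, ca_er=60.0, ip3=0.5, h=0.8, C1=1.0)
    base.update(kw)
    return ModelState(**base)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

class TestGating:
    def test_half_saturation_at_dissociation_constants(self, params):
        m, _, _, _, _ = gating_functions(params.d1, 0.1, params)
        assert m == pytest.approx(0.5)
        _, n, _, _, _ = gating_functions(0.5, params.d5, params)
        assert n == pytest.approx(0.5)

    def test_inactivation_gate_at_zero_ip3(self, params):
        # Q2_gate(0) = d2 d1/d3; h settles to 1/2 at Ca = Q2_gate with
        # tau = 1/(2 a2 Q2_gate)
        q2 = params.d2 * params.d1 / params.d3
        assert q2 == pytest.approx(0.14456, rel=1e-3)
        _, _, h_inf, tau, q2_out = gating_functions(0.0, q2, params)
        assert q2_out == pytest.approx(q2)
        assert h_inf == pytest.approx(0.5)
        assert tau == pytest.approx(1.0 / (params.a2 * 2 * q2), rel=1e-6)
        assert tau == pytest.approx(17.29, rel=1e-3)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            gating_functions(-0.1, 0.1, params)
        with pytest.raises(ValueError):
            gating_functions(0.1, -0.1, params)

    @settings(deadline=None, max_examples=50)
    @given(ip3=st.floats(0, 100), ca=st.floats(0, 100))
    def test_outputs_bounded_and_finite(self, ip3, ca):
        p = ModelParameters()
        m, n, h_inf, tau, q2 = gating_functions(ip3, ca, p)
        for g in (m, n, h_inf):
            assert 0.0 <= g <= 1.0
        assert np.isfinite(tau) and tau > 0
        assert q2 > 0


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

class TestFluxes:
    def test_pump_half_max_at_affinity(self, params):
        assert pump_flux(params.k_pmca, params.v_pmca, params.k_pmca) \
            == pytest.approx(15.0)
        assert pump_flux(params.k_serca, params.v_serca, params.k_serca) \
            == pytest.approx(11.25)
        assert pump_flux(0.0, 30.0, 0.45) == 0.0

    def test_pump_monotone_and_saturating(self, params):
        ca = np.linspace(0, 50, 2000)
        j = pump_flux(ca, params.v_pmca, params.k_pmca)
        assert (np.diff(j) > 0).all()
        assert j[-1] < params.v_pmca
        assert pump_flux(1e6, params.v_pmca, params.k_pmca) \
            == pytest.approx(params.v_pmca, rel=1e-9)

    def test_er_leak(self, params):
        assert er_leak_flux(make_state(ca_er=0.1, ca_i=0.1), params) == 0.0
        assert er_leak_flux(make_state(ca_er=100.0, ca_i=0.1), params) \
            == pytest.approx(0.03 * 99.9)
        a = er_leak_flux(make_state(ca_er=5.0, ca_i=1.0), params)
        b = er_leak_flux(make_state(ca_er=1.0, ca_i=5.0), params)
        assert a == pytest.approx(-b)

    def test_ip3r_flux_zeros(self, params):
        assert ip3r_flux(make_state(ca_er=0.2, ca_i=0.2), params) == 0.0
        assert ip3r_flux(make_state(h=0.0), params) == 0.0

    def test_ip3r_open_probability_biphasic(self, params):
        # at fixed IP3 with h slaved to h_inf(Ca), the open probability has
        # exactly one interior maximum over Ca in (0, 2] (CICR then
        # inactivation)
        ca = np.linspace(1e-4, 2.0, 4000)
        ip3 = 0.5
        _, _, h_inf, _, _ = gating_functions(ip3, ca, params)
        o = ip3r_open_probability(ip3, ca, h_inf, params)
        i_max = int(np.argmax(o))
        assert 0 < i_max < len(ca) - 1
        rising = np.diff(o[:i_max + 1])
        falling = np.diff(o[i_max:])
        assert (rising > 0).all()
        assert (falling < 0).all()

    def test_p2x7_current_and_flux_unit_arithmetic(self, params):
        state = make_state(C1=0.0, Q2=1.0)
        current, flux = p2x7_flux(state, params)
        assert current == pytest.approx(-1.5e-9)
        assert flux == pytest.approx(55.01, rel=1e-3)
        # closed pool: no current
        c0, f0 = p2x7_flux(make_state(), params)
        assert c0 == 0.0 and f0 == 0.0
        # linear in the open fraction
        _, half = p2x7_flux(make_state(C1=0.5, Q2=0.5), params)
        assert half == pytest.approx(flux / 2)


# ---------------------------------------------------------------------------
# Markov scheme
# ---------------------------------------------------------------------------

class TestMarkov:
    @settings(deadline=None, max_examples=30)
    @given(atp=st.floats(0, 1e-1))
    def test_generator_conserves_probability(self, atp):
        g = p2x7_transition_matrix(atp, ModelParameters())
        assert np.abs(g.sum(axis=0)).max() < 1e-12

    def test_negative_atp_rejected(self, params):
        with pytest.raises(ValueError):
            p2x7_transition_matrix(-1e-3, params)

    @pytest.mark.parametrize("state", ["C1", "C4"])
    def test_rest_states_invariant_without_atp(self, params, state):
        # neither the naive nor the sensitized zero-bound state has any
        # outgoing transition at [ATP] = 0
        g = p2x7_transition_matrix(0.0, params)
        v = np.zeros(12)
        v[MARKOV_STATES.index(state)] = 1.0
        assert np.abs(expm(g * 2000.0) @ v - v).max() < 1e-12

    def test_matrix_exponential_matches_ode_propagation(self, params):
        g = p2x7_transition_matrix(1e-3, params)
        v0 = np.zeros(12)
        v0[MARKOV_STATES.index("C1")] = 1.0
        exact = expm(g * 1.0) @ v0
        sol = solve_ivp(lambda t, v: g @ v, (0, 1.0), v0, method="LSODA",
                        rtol=1e-11, atol=1e-13)
        ode = sol.y[:, -1]
        assert np.abs(ode - exact).max() / np.abs(exact).max() < 1e-8

    def test_binding_multiplicities_flag(self):
        p3 = ModelParameters(binding_multiplicities=True)
        p1 = ModelParameters()
        g3 = p2x7_transition_matrix(1e-3, p3)
        g1 = p2x7_transition_matrix(1e-3, p1)
        i, j = MARKOV_STATES.index("C2"), MARKOV_STATES.index("C1")
        assert g3[i, j] == pytest.approx(3 * g1[i, j])

    def test_desensitized_ladder_flag(self):
        p = ModelParameters(desensitized_ladder=False)
        g = p2x7_transition_matrix(1e-3, p)
        i, j = MARKOV_STATES.index("D2"), MARKOV_STATES.index("D1")
        assert g[i, j] == 0.0


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------

class TestFullRhs:
    def test_ip3_stays_zero_without_atp(self, params):
        dy = full_rhs(make_state(ip3=0.0), 0.0, params)
        assert dy[2] == 0.0

    def test_ip3_decays_without_atp(self, params):
        dy = full_rhs(make_state(ip3=2.0), 0.0, params)
        assert dy[2] == pytest.approx(-params.delta * 2.0)

    def test_ip3_closed_form_steady_state(self, params):
        # at [ATP] = k_atp the production is alpha/2, so IP3* = alpha/(2 delta)
        state = make_state(ip3=params.alpha_atp / (2 * params.delta))
        dy = full_rhs(state, params.k_atp * 1e-6, params)  # k_atp uM -> M
        assert dy[2] == pytest.approx(0.0, abs=1e-15)
        assert state.ip3 == pytest.approx(1.5)

    def test_markov_derivatives_sum_to_zero(self, params, rng):
        v = rng.random(12)
        v /= v.sum()
        state = ModelState.from_array(
            np.concatenate([[0.2, 50.0, 1.0, 0.5], v]))
        dy = full_rhs(state, 3e-4, params)
        assert abs(dy[4:].sum()) < 1e-12

    def test_unknown_knockout_rejected(self, params):
        with pytest.raises(ValueError, match="knockout"):
            full_rhs(make_state(), 1e-5, params, knockout="p2y1")

    def test_knockouts_zero_their_flux(self, params):
        state = make_state(C1=0.5, Q2=0.5)
        fv_none = core.compute_fluxes(state.as_array(), 1e-4, params, "none")
        fv_y2 = core.compute_fluxes(state.as_array(), 1e-4, params, "p2y2")
        fv_x7 = core.compute_fluxes(state.as_array(), 1e-4, params, "p2x7")
        assert fv_none.j_ip3r > 0 and fv_none.j_p2x7 > 0
        assert fv_y2.j_ip3r == 0.0 and fv_y2.j_p2x7 == fv_none.j_p2x7
        assert fv_x7.j_p2x7 == 0.0 and fv_x7.j_ip3r == fv_none.j_ip3r

    def test_closed_cell_conserves_total_calcium(self):
        # with no plasma-membrane exchange the model reduces to a closed-cell
        # IP3R/SERCA system; f_c-weighted cytosolic plus ER/(f_er gamma)
        # calcium is a conserved quantity
        p = ModelParameters(j_inleak=0.0, v_pmca=0.0)
        f = rhs_function(1e-5, p, knockout="p2x7")
        y0 = make_state(ca_i=0.3, ca_er=40.0, ip3=0.4, h=0.7).as_array()
        total0 = y0[0] / p.f_c + y0[1] / (p.f_er * p.gamma)
        sol = solve_ivp(f, (0, 200.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]
        total = y[0] / p.f_c + y[1] / (p.f_er * p.gamma)
        assert total == pytest.approx(total0, rel=1e-8)
        assert abs(y0[0] - y[0]) > 1e-3  # the system actually moved


class TestModelState:
    def test_roundtrip_and_validation(self):
        s = make_state()
        assert ModelState.from_array(s.as_array()) == s
        s.validate()
        with pytest.raises(ValueError, match="sum to 1"):
            make_state(C1=0.5).validate()
        with pytest.raises(ValueError, match="non-negative"):
            make_state(ca_i=-0.1).validate()
        assert make_state(C1=0.0, Q1=0.25, Q4=0.25, D1=0.5).open_fraction \
            == pytest.approx(0.5)
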