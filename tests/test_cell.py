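"""Unit tests of the potassium-bath neuron: currents, RHS, integrator."""

import math

import numpy as np
import pytest

from hybridbrain import (CellParams, CellState, IntegrationError, cell_rhs,
                         ionic_currents, nernst_potential, resting_state,
                         simulate_cell)
from hybridbrain.cell import (derived_concentrations, gating_h_of_n,
                              gating_m_inf, gating_n_inf)


# --------------------------------------------------------------------------
# independent straight-line re-implementation of the printed formulas,
# written against the equations alone (oracle for ionic_currents/cell_rhs)
# --------------------------------------------------------------------------

def oracle_currents_and_rhs(V, n, dKi, Kg, p: CellParams, i_syn=0.0):
    Ki = p.K0_i + dKi
    Nai = p.Na0_i - dKi
    Cli = p.Cl0_i
    Ko = p.K0_o - p.beta_vol * dKi + Kg
    Nao = p.Na0_o + p.beta_vol * dKi
    Clo = p.Cl0_o
    EK = p.C_nernst * math.log(Ko / Ki)
    ENa = p.C_nernst * math.log(Nao / Nai)
    ECl = p.C_nernst * math.log(Cli / Clo)
    m = 1.0 / (1.0 + math.exp(-(24.0 + V) / 12.0))
    h = 1.1 - 1.0 / (1.0 + math.exp(3.2 - 8.0 * n))
    iK = (p.g0_K * n + p.gl_K) * (V - EK)
    iNa = (p.g0_Na * m * h + p.gl_Na) * (V - ENa)
    iCl = p.g0_Cl * (V - ECl)
    ipump = p.rho / ((1 + math.exp((21.0 - Nai) / 2.0))
                     * (1 + math.exp(5.5 - Ko)))
    dV = -(iK + iNa + iCl + ipump - i_syn) / p.cm
    ninf = 1.0 / (1.0 + math.exp(-(19.0 + V) / 18.0))
    dn = (ninf - n) / p.tau_n
    ddKi = -p.gamma_ion * (iK - p.pump_K_stoich * ipump)
    dKg = p.epsilon * (p.K_bath - Ko)
    return (iK, iNa, iCl, ipump), (dV, dn, ddKi, dKg)


SNAPSHOTS = [
    (-70.0, 0.05, 0.0, 0.0),
    (-30.0, 0.40, -0.4, 1.5),
    (10.0, 0.80, 0.3, -0.5),
    (-55.0, 0.10, 0.25, 3.0),
]


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_potential(7.7, 7.7) == 0.0

    def test_log_scale(self):
        assert nernst_potential(math.e * 3.0, 3.0, 26.64) == pytest.approx(26.64)

    def test_physiological_potassium(self):
        # 26.64 * ln(4/140)
        assert nernst_potential(4.0, 140.0, 26.64) == pytest.approx(-94.714, abs=1e-3)

    @pytest.mark.parametrize("Xo,Xi", [(0.0, 1.0), (1.0, 0.0), (-4.0, 140.0)])
    def test_nonpositive_concentration_rejected(self, Xo, Xi):
        with pytest.raises(ValueError):
            nernst_potential(Xo, Xi)


class TestIonicCurrents:
    @pytest.mark.parametrize("snap", SNAPSHOTS)
    def test_matches_independent_oracle(self, cell_params, snap):
        V, n, dKi, Kg = snap
        got = ionic_currents(CellState(V, n, dKi, Kg), cell_params)
        want, _ = oracle_currents_and_rhs(V, n, dKi, Kg, cell_params)
        assert got == pytest.approx(want, rel=1e-12)

    def test_potassium_current_vanishes_at_reversal(self, cell_params):
        st = CellState(V=0.0, n=0.3)
        c = derived_concentrations(st, cell_params)
        EK = nernst_potential(c["K_o"], c["K_i"], cell_params.C_nernst)
        iK, *_ = ionic_currents(CellState(V=EK, n=0.3), cell_params)
        assert iK == pytest.approx(0.0, abs=1e-12)

    def test_pump_limit_at_depleted_concentrations(self, cell_params):
        # Na_i -> 0 and K_o -> 0: sigmoid product -> 1/((1+e^10.5)(1+e^5.5))
        p = cell_params
        dKi = p.Na0_i - 1e-9           # drives Na_i ~ 0
        Kg = -(p.K0_o - p.beta_vol * dKi) + 1e-9   # drives K_o ~ 0
        *_, ipump = ionic_currents(CellState(-70.0, 0.05, dKi, Kg), p)
        limit = p.rho / ((1 + math.exp(10.5)) * (1 + math.exp(5.5)))
        assert ipump == pytest.approx(limit, rel=1e-6)
        # analytic limit of the sigmoid product
        assert ipump / p.rho == pytest.approx(1.1207e-7, rel=1e-3)

    def test_nan_state_raises(self, cell_params):
        with pytest.raises(ValueError, match="NaN|Inf|finite"):
            ionic_currents(CellState(float("nan"), 0.1), cell_params)


class TestCellRhs:
    @pytest.mark.parametrize("snap", SNAPSHOTS)
    @pytest.mark.parametrize("i_syn", [0.0, 2.5])
    def test_matches_independent_oracle(self, cell_params, snap, i_syn):
        V, n, dKi, Kg = snap
        got = cell_rhs(CellState(V, n, dKi, Kg), cell_params, i_syn)
        _, want = oracle_currents_and_rhs(V, n, dKi, Kg, cell_params, i_syn)
        assert got == pytest.approx(want, rel=1e-12)

    def test_bath_at_baseline_freezes_buffer(self, cell_params):
        p = CellParams(K_bath=cell_params.K0_o)
        d = cell_rhs(CellState(-70.0, 0.05, 0.0, 0.0), p)
        assert d[3] == 0.0  # dKg/dt

    def test_flux_balance_freezes_internal_potassium(self, cell_params):
        # choose V = E_K + pump_K_stoich*i_pump/g_K so that i_K equals the
        # pump contribution exactly
        st = CellState(V=-70.0, n=0.05)
        p = cell_params
        c = derived_concentrations(st, p)
        EK = nernst_potential(c["K_o"], c["K_i"], p.C_nernst)
        *_, ipump = ionic_currents(st, p)
        gK = p.g0_K * st.n + p.gl_K
        V_bal = EK + p.pump_K_stoich * ipump / gK
        d = cell_rhs(CellState(V_bal, st.n), p)
        assert d[2] == pytest.approx(0.0, abs=1e-15)

    def test_rhs_matches_finite_difference_of_trajectory(self, cell_params):
        p = cell_params.with_bath(9.5)
        tr = simulate_cell(p, T=50.0, dt=0.0025)
        k = 5000  # mid-trajectory sample
        st = CellState(tr.V[k], tr.n[k], tr.dKi[k], tr.Kg[k])
        dV_num = (tr.V[k + 1] - tr.V[k - 1]) / (2 * tr.dt)
        dV_rhs = cell_rhs(st, p)[0]
        assert dV_rhs == pytest.approx(dV_num, rel=5e-3, abs=5e-3)


class TestBookkeepingInvariants:
    def test_conservation_holds_along_trajectory(self, cell_params):
        p = cell_params.with_bath(17.0)
        tr = simulate_cell(p, T=2000.0, dt=0.0125, record_every=40)
        conc_Na = p.Na0_i - tr.dKi
        conc_K = p.K0_i + tr.dKi
        # bookkeeping identities: algebraic, so exact to rounding
        np.testing.assert_allclose(conc_Na + tr.dKi, p.Na0_i, rtol=1e-15)
        np.testing.assert_allclose(conc_K - tr.dKi, p.K0_i, rtol=1e-15)

    def test_frozen_slow_subsystem(self, cell_params):
        from dataclasses import replace

        p = replace(cell_params.with_bath(12.0), epsilon=0.0, gamma_ion=0.0)
        tr = simulate_cell(p, T=500.0, dt=0.0125, record_every=100)
        assert np.all(tr.dKi == tr.dKi[0])
        assert np.all(tr.Kg == tr.Kg[0])

    def test_convergence_under_dt_halving(self, cell_params):
        # settled resting trajectory: V(t=1 s) must be step-size independent
        p = cell_params.with_bath(4.0)
        settle = simulate_cell(p, T=3000.0, dt=0.0125)
        from hybridbrain import CellState

        start = CellState(V=settle.V[-1], n=settle.n[-1],
                          dKi=settle.dKi[-1], Kg=settle.Kg[-1])
        v1 = simulate_cell(p, T=1000.0, dt=0.0125, initial=start).V[-1]
        v2 = simulate_cell(p, T=1000.0, dt=0.00625, initial=start).V[-1]
        assert abs(v1 - v2) < 0.1  # mV


class TestSimulateCell:
    def test_trace_shape_and_determinism(self, cell_params):
        tr1 = simulate_cell(cell_params, T=100.0, dt=0.0125)
        tr2 = simulate_cell(cell_params, T=100.0, dt=0.0125)
        assert len(tr1.t) == int(100.0 / 0.0125) + 1
        assert np.array_equal(tr1.V, tr2.V)

    def test_divergence_reported_with_time(self, cell_params):
        from dataclasses import replace

        bad = CellState(V=-70.0, n=0.05)
        p = replace(cell_params, cm=1e-6)  # absurd capacitance -> blow-up
        with pytest.raises(IntegrationError, match="t ="):
            simulate_cell(p, T=10.0, dt=0.0125, initial=bad)

    def test_invalid_steps_rejected(self, cell_params):
        with pytest.raises(ValueError):
            simulate_cell(cell_params, T=10.0, dt=0.0)
        with pytest.raises(ValueError):
            simulate_cell(cell_params, T=0.001, dt=0.0125)

    def test_resting_state_is_stationary_when_rest_exists(self, cell_params):
        from dataclasses import replace

        # without sodium channels the fast subsystem must have a true rest
        p = replace(cell_params, g0_Na=0.0, gl_Na=0.0)
        st = resting_state(p)
        d = cell_rhs(st, p)
        assert abs(d[0]) < 1e-6  # dV/dt ~ 0 at the computed rest

    def test_external_drive_depolarizes(self, cell_params):
        # subthreshold inward drive raises the mean potential
        p = cell_params.with_bath(4.0)
        quiet = simulate_cell(p, T=200.0, dt=0.0125)
        driven = simulate_cell(p, T=200.0, dt=0.0125,
                               i_syn_fn=lambda t: 3.0 if t > 100.0 else 0.0)
        m = quiet.t > 150.0
        assert driven.V[m].mean() > quiet.V[m].mean() + 0.2


class TestGatingShapes:
    def test_gates_bounded_on_physiological_range(self):
        V = np.linspace(-120.0, 60.0, 200)
        for v in V:
            assert 0.0 < gating_n_inf(v) < 1.0
            assert 0.0 < gating_m_inf(v) < 1.0
        for n in np.linspace(0.0, 1.0, 50):
            assert 0.0 < gating_h_of_n(n) <= 1.1

    def test_h_decreases_with_n(self):
        n = np.linspace(0.0, 1.0, 50)
        h = np.array([gating_h_of_n(x) for x in n])
        assert np.all(np.diff(h) < 0)
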