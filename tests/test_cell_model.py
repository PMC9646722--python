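"""Cell-model unit tests: currents, gates, homeostasis, integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from paceopt import (CellState, ModelParameters, RosterError, ScalingFactors,
                     StateIntegrityError, ca_total, channel_current,
                     gate_derivative, homeostasis_update, integrate, roster,
                     state_derivative, total_current)
from paceopt.model import formulation as fm


def spec_of(name, params=None):
    return next(s for s in roster(params) if s.name == name)


class TestScalingFactors:
    def test_implicit_unity_and_override(self):
        sf = ScalingFactors(Kr=1.2)
        assert sf["Kr"] == 1.2
        assert sf["CaL"] == 1.0
        vec = sf.vector()
        assert vec[list(fm.CHANNEL_NAMES).index("Kr")] == 1.2
        assert np.sum(vec == 1.0) == 8

    @pytest.mark.parametrize("bad", [0.0, -0.5, np.nan, np.inf])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            ScalingFactors(Kr=bad)

    def test_rejects_transporters_and_unknown(self):
        for name in ("NaK", "NCX", "CaT"):
            with pytest.raises(RosterError):
                ScalingFactors({name: 1.1})


class TestChannelCurrent:
    def test_hand_evaluated_ohmic_current(self):
        # Gbar 1 nS, pO 0.5, V -60, E -80 -> 10 pA outward
        state = CellState.initial()
        state.y[fm.IV] = -60.0
        state.y[fm.IY] = 0.5  # the single ha gate
        p = ModelParameters(overrides={"G_ha": 1.0, "E_ha": -80.0})
        i = channel_current(spec_of("ha", p), ScalingFactors(), state, p)
        assert i == pytest.approx(10.0, rel=1e-12)

    def test_zero_at_reversal_potential(self, params):
        state = CellState.initial(params)
        state.y[fm.IV] = params["E_bNSC"]
        i = channel_current(spec_of("bNSC"), ScalingFactors(), state, params)
        assert i == 0.0
        # Nernst-ruled channel: set V to E_K
        e_k = fm.nernst(1, params["K_o"], state.K_i)
        state.y[fm.IV] = e_k
        for name in ("K1", "Kr", "Ks", "Kur", "Kto"):
            assert channel_current(spec_of(name), ScalingFactors(),
                                   state, params) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_sf(self, settled_state, params):
        base = channel_current(spec_of("CaL"), ScalingFactors(),
                               settled_state, params)
        double = channel_current(spec_of("CaL"), ScalingFactors(CaL=2.0),
                                 settled_state, params)
        assert double == pytest.approx(2.0 * base, rel=1e-12)

    def test_transporter_rejected(self, settled_state):
        with pytest.raises(RosterError):
            channel_current(spec_of("NaK"), ScalingFactors(), settled_state)

    def test_gate_out_of_range_rejected(self, params):
        state = CellState.initial(params)
        state.y[fm.IM] = 1.5
        with pytest.raises(StateIntegrityError):
            channel_current(spec_of("Na"), ScalingFactors(), state, params)


class TestGateDerivative:
    def test_hand_evaluated(self):
        # alpha 0.2/ms, beta 0.1/ms at some V for some scheme is not directly
        # settable; check the defining formula through gate_rates instead
        v = -40.0
        alpha, beta = fm.gate_rates("m", v)
        po = 0.1
        assert gate_derivative(po, v, "m") == pytest.approx(
            alpha * (1 - po) - beta * po, rel=1e-12)

    @pytest.mark.parametrize("scheme", fm.GATE_NAMES)
    @pytest.mark.parametrize("v", [-90.0, -60.0, -20.0, 20.0])
    def test_fixed_point_and_boundaries(self, scheme, v):
        alpha, beta = fm.gate_rates(scheme, v)
        assert alpha >= 0 and beta >= 0
        po_star = alpha / (alpha + beta)
        assert gate_derivative(po_star, v, scheme) == pytest.approx(0, abs=1e-12)
        assert gate_derivative(0.0, v, scheme) >= 0
        assert gate_derivative(1.0, v, scheme) <= 0

    def test_invalid_po(self):
        with pytest.raises(StateIntegrityError):
            gate_derivative(1.2, -40.0, "m")


class TestTotalCurrent:
    def test_breakdown_sums_to_total(self, settled_state, params):
        itot, breakdown = total_current(settled_state, ScalingFactors(), params)
        assert len(breakdown) == 11
        assert itot == pytest.approx(sum(breakdown.values()), abs=1e-12)

    def test_roster_is_the_eleven_currents(self):
        names = [s.name for s in roster()]
        assert names == ["Na", "CaL", "ha", "K1", "Kr", "Ks", "Kur", "Kto",
                         "bNSC", "NaK", "NCX"]


class TestStateDerivative:
    def test_dv_is_minus_itot_over_cm(self, settled_state, params):
        itot, _ = total_current(settled_state, ScalingFactors(), params)
        dy = state_derivative(settled_state, ScalingFactors(), params)
        assert dy[fm.IV] == pytest.approx(-itot / params["C_m"], rel=1e-12)

    def test_outward_current_hyperpolarizes(self, params):
        # a state dominated by outward K1 current (depolarized, gates shut)
        state = CellState.initial(params)
        state.y[fm.IV] = -50.0
        for i in range(1, 12):
            state.y[i] = 1e-6
        itot, _ = total_current(state, ScalingFactors(K1=10.0), params)
        dy = state_derivative(state, ScalingFactors(K1=10.0), params)
        if itot > 0:
            assert dy[fm.IV] < 0


class TestHomeostasis:
    def test_setpoint_is_equilibrium(self, params):
        state = CellState.initial(params)
        state.y[fm.INAI] = params["std_Nai"]
        # adjust one Ca compartment so total cell Ca sits exactly on 79 amol
        target = params["std_Catot"] / 1000.0
        other = (state.Ca_jnc * params["vol_jnc"] + state.Ca_iz * params["vol_iz"]
                 + state.Ca_blk * params["vol_blk"]
                 + state.Ca_SRrl * params["vol_SRrl"])
        state.y[fm.ICAUP] = (target - other) / params["vol_SRup"]
        out = homeostasis_update(state, params)
        assert out.crf_NaK == pytest.approx(state.crf_NaK, abs=1e-12)
        assert out.crf_NCX == pytest.approx(state.crf_NCX, abs=1e-12)

    def test_hand_evaluated_increments(self, params):
        state = CellState.initial(params)
        state.y[fm.INAI] = 6.0  # 0.1 mM below the 6.1 reference
        out = homeostasis_update(state, params)
        assert out.crf_NaK - state.crf_NaK == pytest.approx(-0.03, rel=1e-9)
        # total Ca of 80 amol, reference 79 -> +0.008
        state2 = CellState.initial(params)
        state2.y[fm.ICAJNC:fm.ICARL + 1] = 0.0
        state2.y[fm.ICAUP] = (80.0 / 1000.0) / params["vol_SRup"]
        with np.errstate(all="ignore"):
            out2 = homeostasis_update(state2, params)
        assert out2.crf_NCX - state2.crf_NCX == pytest.approx(0.008, rel=1e-9)

    def test_floor_clip_warns(self, params):
        state = CellState.initial(params)
        state.y[fm.INAI] = 2.0  # far below reference: feedback drives crf < 0
        with pytest.warns(UserWarning):
            out = homeostasis_update(state, params)
        assert out.crf_NaK == params["crf_floor"]


class TestCaTotal:
    def test_zero_cell(self, params):
        state = CellState.initial(params)
        state.y[fm.ICAJNC:fm.ICARL + 1] = 0.0
        assert ca_total(state, params) == 0.0

    def test_linearity(self, settled_state, params):
        doubled = settled_state.copy()
        doubled.y[fm.ICAJNC:fm.ICARL + 1] *= 3.0
        assert ca_total(doubled, params) == pytest.approx(
            3.0 * ca_total(settled_state, params), rel=1e-12)

    def test_hand_set_compartments_brute_force(self):
        p = ModelParameters()
        state = CellState.initial(p)
        concs = [0.011, 0.005, 0.002, 0.73, 1.9]
        state.y[fm.ICAJNC:fm.ICARL + 1] = concs
        vols = [p["vol_jnc"], p["vol_iz"], p["vol_blk"],
                p["vol_SRup"], p["vol_SRrl"]]
        expected = 1000.0 * sum(c * v for c, v in zip(concs, vols))
        assert ca_total(state, p) == pytest.approx(expected, rel=1e-12)


class TestIntegrate:
    def test_quasi_stable_rhythm_continues(self, settled_state, params):
        tr1, final1, ct1 = integrate(settled_state, ScalingFactors(), params,
                                     n_cycles=6)
        tr2, _, ct2 = integrate(final1, ScalingFactors(), params, n_cycles=6)
        cl1 = np.diff(ct1).mean()
        cl2 = np.diff(ct2).mean()
        assert abs(cl1 - cl2) / cl1 < 5e-4

    def test_gates_bounded_along_trajectory(self, settled_state, params):
        trace, _, _ = integrate(settled_state, ScalingFactors(), params,
                                n_cycles=3, record_states=True)
        states = trace.meta["states"]
        gates = states[:, 1:12]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_quiescent_signalled_not_raised(self, settled_state, params):
        # removing the depolarizing background and funny currents silences it
        sf = ScalingFactors(bNSC=1e-6, ha=1e-6, CaL=1e-6, Na=1e-6)
        trace, _, _ = integrate(settled_state, sf, params, n_cycles=5)
        assert trace.quiescent

    def test_grid_is_exact_tenth_ms(self, baseline_target):
        t = baseline_target.t
        assert np.allclose(np.diff(t), 0.1, atol=1e-12)

    def test_kernel_consistent_with_reference_rhs(self, settled_state, params):
        """The compiled kernel and the numpy RHS describe the same model."""
        sf = ScalingFactors()
        y0 = settled_state.y.copy()

        def rhs(t, y):
            return state_derivative(CellState(y), sf, params)

        horizon = 400.0  # ms, covers SDD and part of the upstroke approach
        sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=True)
        trace, _, _ = integrate(settled_state, sf,
                                ModelParameters(homeostasis=False),
                                n_cycles=1, max_ms=horizon + 1)
        n = min(int(horizon / 0.1), len(trace.vm) - 1)
        v_ref = sol.sol(np.arange(n) * 0.1)[0]
        v_ker = trace.vm[:n]
        assert np.max(np.abs(v_ref - v_ker)) < 0.5  # mV, discretization level

    def test_refinement_stability(self, settled_state):
        """Halving dt changes the waveform below the objective floor scale."""
        from paceopt import mse
        coarse = ModelParameters(homeostasis=False)
        fine = ModelParameters(dt=0.01, homeostasis=False)
        tr_c, _, _ = integrate(settled_state, ScalingFactors(), coarse,
                               n_cycles=4)
        tr_f, _, _ = integrate(settled_state, ScalingFactors(), fine,
                               n_cycles=4)
        assert mse(tr_f, tr_c) < 0.05  # mV^2


class TestSpontaneousBaseline:
    def test_metrics_in_observed_ranges(self, baseline_target):
        """sf = 1 produces APs inside the observed hiPSC metric bands."""
        from paceopt import ap_metrics
        m = ap_metrics(baseline_target)
        assert 239.5 <= m.CL <= 1326.0
        assert -87.4 <= m.MDP <= -61.5
        assert 13.8 <= m.OS <= 33.0
        assert 0 < m.APD_minus20 < m.CL

    def test_baseline_reaches_reference_ion_levels(self, settled_state, params):
        assert settled_state.Na_i == pytest.approx(params["std_Nai"], rel=5e-4)
        assert ca_total(settled_state, params) == pytest.approx(
            params["std_Catot"], rel=5e-4)
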