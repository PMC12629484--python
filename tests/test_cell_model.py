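"""Ionic-model unit and property tests: mixture law, gating, stepping, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriacal import cell_model as cm
from atriacal import _model


def random_valid_state(rng):
    y = cm.default_state()
    y[0] = rng.uniform(-90.0, 40.0)
    y[1:16] = rng.uniform(0.0, 1.0, 15)
    y[16] = rng.uniform(5.0, 20.0)     # Na_i
    y[17] = rng.uniform(120.0, 150.0)  # K_i
    y[18] = rng.uniform(5e-5, 1e-2)    # Ca_i
    y[19:] = rng.uniform(0.1, 10.0, 2)
    return y


class TestIcalMixture:
    @settings(max_examples=50, deadline=None)
    @given(f=st.floats(0.0, 1.0), s=st.floats(0.0, 1.0),
           seed=st.integers(0, 2**31 - 1))
    def test_mixture_equals_single_conductance_scaling(self, f, s, seed):
        """(1-f)*WT + f*mut equals WT scaled by (1-f)+f*s, to machine precision."""
        y = random_valid_state(np.random.default_rng(seed))
        mixed = cm.compute_ical(y, cm.IcalParams(f=f, s_mut=s))
        wt = cm.compute_ical(y, cm.IcalParams())
        assert mixed == pytest.approx(((1.0 - f) + f * s) * wt, rel=1e-12, abs=1e-300)

    def test_known_mixture_points(self):
        y = random_valid_state(np.random.default_rng(0))
        wt = cm.compute_ical(y, cm.IcalParams(f=0.0, s_mut=0.07))
        hom = cm.compute_ical(y, cm.IcalParams(f=1.0, s_mut=0.07))
        het = cm.compute_ical(y, cm.IcalParams(f=0.5, s_mut=0.07))
        assert hom == pytest.approx(0.07 * wt, rel=1e-12)
        assert het == pytest.approx(0.5 * (wt + hom), rel=1e-12)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(cm.ConfigurationError):
            cm.IcalParams(f=1.5)
        with pytest.raises(cm.ConfigurationError):
            cm.IcalParams(s_mut=-0.1)


class TestCurrents:
    def test_component_sum_matches_total(self, wt_params):
        rng = np.random.default_rng(1)
        for _ in range(5):
            cur = cm.compute_currents(random_valid_state(rng), wt_params)
            total = sum(cur[name] for name in cm.CURRENT_NAMES)
            assert cur["Iion_tot"] == pytest.approx(total, rel=1e-12)

    def test_ical_negligible_at_rest(self, wt_params, relaxed_wt_state):
        cur = cm.compute_currents(relaxed_wt_state, wt_params)
        assert abs(cur["ICaL"]) < 0.05  # activation gate closed near -80 mV

    def test_ical_plateau_density_matches_reported_scale(self, wt_steady_beat,
                                                         wt_params):
        """Peak I_CaL during a paced WT AP is of the reported ~8 pA/pF order."""
        _, state, _ = wt_steady_beat
        eff = wt_params.effective_vector()
        y = state.copy()
        out = np.empty(18)
        peak = 0.0
        for k in range(20000):  # 200 ms following a fresh 2-ms stimulus
            _model.step_rl(y, eff, 20.0 if k < 200 else 0.0, 0.01)
            _model.compute_currents_arr(y, eff, out)
            peak = min(peak, out[0])
        assert -14.0 < peak < -4.0

    def test_unknown_region_rejected(self):
        with pytest.raises(cm.ConfigurationError):
            cm.make_regional_params("LV", "WT")
        with pytest.raises(cm.ConfigurationError):
            cm.make_regional_params("RA", "notavariant")


class TestRegionalParams:
    def test_reference_region_is_unscaled(self):
        p = cm.make_regional_params("RA", "WT")
        assert all(v == 1.0 for v in p.regional_scalings.values())
        assert p.ical.f == 0.0

    @pytest.mark.parametrize("variant,s", [("G490R", 0.07),
                                           ("A39V_exon8A", 0.13),
                                           ("A39V_exon8", 0.20)])
    def test_variant_relative_conductances(self, variant, s):
        p = cm.make_regional_params("RA", variant, f=1.0)
        assert p.ical.s_mut == s
        assert p.ical.f == 1.0

    def test_wt_forces_zero_mixture(self):
        assert cm.make_regional_params("RA", "WT", f=0.7).ical.f == 0.0

    def test_junction_regions_scale_conductances(self):
        ct = cm.make_regional_params("CT", "G490R", 0.5)
        ra = cm.make_regional_params("RA", "G490R", 0.5)
        assert ct.effective_vector()[6] == pytest.approx(
            1.68 * ra.effective_vector()[6])


class TestStepping:
    def test_resting_fixed_point(self, wt_params, relaxed_wt_state):
        y1 = cm.step_cell(relaxed_wt_state, 0.0, 0.01, wt_params)
        assert abs(y1[0] - relaxed_wt_state[0]) < 1e-6

    def test_gates_stay_bounded(self, wt_params):
        rng = np.random.default_rng(3)
        y = random_valid_state(rng)
        eff = wt_params.effective_vector()
        for k in range(2000):
            _model.step_rl(y, eff, 20.0 if k < 200 else 0.0, 0.01)
        assert np.all(y[1:16] >= 0.0) and np.all(y[1:16] <= 1.0)
        assert np.all(y[16:] > 0.0)

    def test_rush_larsen_is_exact_for_frozen_rates(self):
        """With rates frozen at fixed Vm, the gate follows exp relaxation."""
        inf = np.empty(12)
        tau = np.empty(12)
        _model.gate_rates(-20.0, inf, tau)
        g0, dt, n = 0.1, 0.5, 40
        g = g0
        for _ in range(n):
            g = inf[3] + (g - inf[3]) * np.exp(-dt / tau[3])
        expected = inf[3] + (g0 - inf[3]) * np.exp(-n * dt / tau[3])
        assert g == pytest.approx(expected, rel=1e-12)

    def test_blowup_raises_named_error(self, wt_params):
        y = cm.default_state()
        y[0] = 1.0e8  # absurd Vm drives the exchanger terms to overflow
        with pytest.raises(cm.IntegrationBlowupError):
            y = cm.step_cell(y, 0.0, 0.01, wt_params)
            cm.step_cell(y, 0.0, 0.01, wt_params)

    def test_resting_stability_10s(self, wt_params, relaxed_wt_state):
        from atriacal._sim import node_states, run
        Y, eff = node_states(wt_params, 1)
        Y[0] = relaxed_wt_state
        v0 = Y[0, 0]
        run(Y, eff, [], 10000.0)
        assert abs(Y[0, 0] - v0) < 1.0


class TestAdaptiveSolverOracle:
    def test_unpaced_relaxation_matches_reference_integrator(self, wt_params):
        from scipy.integrate import solve_ivp
        eff = wt_params.effective_vector()
        y0 = cm.default_state()
        sol = solve_ivp(lambda t, y: _model.derivatives(y, eff, 0.0),
                        (0.0, 1000.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=True)
        assert sol.success
        y = y0.copy()
        err = 0.0
        for k in range(100000):
            _model.step_rl(y, eff, 0.0, 0.01)
            if (k + 1) % 1000 == 0:
                err = max(err, abs(y[0] - sol.sol((k + 1) * 0.01)[0]))
        assert err < 0.5

    def test_paced_ap_matches_reference_integrator(self, wt_params):
        """One paced AP at dt=0.01 ms stays within 1 mV of an adaptive solve."""
        from scipy.integrate import solve_ivp
        eff = wt_params.effective_vector()
        y0 = cm.default_state()

        # integrate the stimulated and free segments separately so the
        # reference solver never steps across the stimulus discontinuity
        sol1 = solve_ivp(lambda t, y: _model.derivatives(y, eff, -20.0),
                         (0.0, 2.0), y0, method="LSODA", rtol=1e-9,
                         atol=1e-12, dense_output=True)
        sol2 = solve_ivp(lambda t, y: _model.derivatives(y, eff, 0.0),
                         (2.0, 400.0), sol1.y[:, -1], method="LSODA",
                         rtol=1e-9, atol=1e-12, dense_output=True)
        assert sol1.success and sol2.success

        def ref(t):
            return (sol1.sol(t) if t <= 2.0 else sol2.sol(t))[0]

        # during the upstroke (~200 mV/ms) a microsecond-scale phase shift
        # between the two integrators shows up as a large apparent Vm error,
        # so the voltage comparison excludes a 3-ms window around it and the
        # upstroke timing is checked separately
        tg = np.arange(0.05, 400.0, 0.05)
        vref = np.array([ref(t) for t in tg])
        t_up_ref = tg[np.argmax(np.gradient(vref, 0.05))]
        y = y0.copy()
        err = 0.0
        v_prev, t_up = y[0], None
        for k in range(40000):
            t = (k + 1) * 0.01
            stim = 20.0 if k * 0.01 < 2.0 else 0.0
            _model.step_rl(y, eff, stim, 0.01)
            if t_up is None and v_prev < -40.0 <= y[0]:
                t_up = t
            v_prev = y[0]
            if (k + 1) % 100 == 0 and abs(t - t_up_ref) > 3.0:
                err = max(err, abs(y[0] - ref(t)))
        assert err < 1.0
        t_up_oracle = tg[np.argmax(vref >= -40.0)]
        assert abs(t_up - t_up_oracle) < 0.2
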