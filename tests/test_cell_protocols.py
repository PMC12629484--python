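"""Single-cell protocol tests: pacing, biomarkers, ERP, restitution."""

import numpy as np
import pytest

from atriacal import cell_protocols as cp
from atriacal.cell_model import make_regional_params, with_mixture
from conftest import trapezoid_trace


def mutant_params(f):
    return with_mixture(make_regional_params("RA", "G490R", f), f)


class TestPacing:
    def test_steady_pacing_converges(self, wt_params, wt_steady_beat):
        """The final-beat APD90 is stable: extending 50 -> 65 beats moves it
        by less than the per-beat drift bound (1 ms/beat)."""
        trace50, _, cap = wt_steady_beat
        assert cap
        trace65, _, _ = cp.pace_to_steady(wt_params, 1000.0, n_beats=65)
        a50 = cp.ap_biomarkers(trace50).APD90
        a65 = cp.ap_biomarkers(trace65).APD90
        assert abs(a65 - a50) < 15.0  # < 1 ms per added beat

    def test_zero_amplitude_stimulus_fails_capture(self, wt_params):
        _, _, captured = cp.pace_to_steady(wt_params, 1000.0, n_beats=3,
                                           stim_amp=0.0)
        assert not captured

    def test_homozygous_ap_is_triangular_and_short(self, wt_steady_beat):
        """f=1 abolishes the plateau: far shorter APD90, no dome (monotonic
        repolarisation after the overshoot)."""
        trace_wt, _, _ = wt_steady_beat
        trace, _, cap = cp.pace_to_steady(mutant_params(1.0), 1000.0)
        assert cap
        b_wt = cp.ap_biomarkers(trace_wt)
        b = cp.ap_biomarkers(trace)
        assert b.APD90 < 0.6 * b_wt.APD90
        # triangular shape: Vm never re-rises by more than 1 mV after the peak
        v = trace.vm
        ipk = int(np.argmax(v))
        running_min = np.minimum.accumulate(v[ipk:])
        assert np.max(v[ipk:] - running_min) < 1.0


class TestBiomarkers:
    def test_closed_form_on_synthetic_trapezoid(self):
        tr = trapezoid_trace(rmp=-80.0, peak=20.0, upstroke_ms=1.0,
                             plateau_ms=100.0, repol_ms=120.0)
        b = cp.ap_biomarkers(tr)
        assert b.RMP == pytest.approx(-80.0, abs=1e-9)
        assert b.APA == pytest.approx(100.0, abs=1e-9)
        # MUV: 100 mV over 1 ms = 100 V/s
        assert b.MUV == pytest.approx(100.0, rel=0.05)
        # APD90: upstroke midpoint to 90% repolarisation on the linear ramp
        expected = 0.5 + 100.0 + 0.9 * 120.0
        assert b.APD90 == pytest.approx(expected, abs=2.0)

    def test_flat_trace_raises(self):
        tr = cp.Trace(0.1, np.full(1000, -80.0), stim_times=(10.0,))
        with pytest.raises(ValueError):
            cp.ap_biomarkers(tr)


class TestERP:
    def test_erp_close_to_but_above_apd(self, wt_params, wt_steady_beat):
        trace, _, _ = wt_steady_beat
        apd = cp.ap_biomarkers(trace).APD90
        erp = cp.measure_erp_cell(wt_params, 1000.0)
        assert erp > 0.9 * apd
        assert erp < 1.5 * apd

    def test_bisection_agrees_with_linear_scan(self, wt_params):
        erp_b = cp.measure_erp_cell(wt_params, 1000.0, resolution=2.0)
        erp_s = cp.measure_erp_cell(wt_params, 1000.0, resolution=2.0,
                                    si_grid=True)
        assert abs(erp_b - erp_s) <= 2.0

    def test_erp_decreases_with_mixture_fraction(self):
        erps = [cp.measure_erp_cell(mutant_params(f), 1000.0, resolution=2.0)
                for f in (0.0, 0.5, 1.0)]
        assert erps[0] > erps[1] > erps[2]


class TestRestitution:
    def test_flat_synthetic_curve_has_zero_slope(self):
        curve = cp.RestitutionCurve("DI_ms",
                                    [(di, 200.0, None) for di in (50, 100,
                                                                  200, 400)])
        assert curve.max_slope() == 0.0

    def test_exponential_curve_slope_matches_analytic(self):
        """APD(DI) = 250 - 120*exp(-DI/60): max centred-difference slope on
        the sampled grid matches the analytic derivative within 5 %."""
        di = np.array([20.0, 30, 40, 60, 80, 120, 180, 260, 360, 500])
        apd = 250.0 - 120.0 * np.exp(-di / 60.0)
        curve = cp.RestitutionCurve("DI_ms", [(x, y, None)
                                              for x, y in zip(di, apd)])
        # the centred difference at the smallest interior DI
        k = 1
        expected = (apd[2] - apd[0]) / (di[2] - di[0])
        assert curve.max_slope() == pytest.approx(expected, rel=1e-12)
        analytic = 2.0 * np.exp(-di[k] / 60.0)
        assert curve.max_slope() == pytest.approx(analytic, rel=0.05)

    def test_dynamic_restitution_flattens_with_ical_deficiency(self):
        bcls = np.array([700.0, 500.0, 400.0, 340.0, 300.0])
        _, slope_wt = cp.restitution(make_regional_params("RA", "WT"),
                                     bcls=bcls, beats_per_bcl=8)
        _, slope_mut = cp.restitution(mutant_params(1.0), bcls=bcls,
                                      beats_per_bcl=8)
        assert np.isfinite(slope_wt) and np.isfinite(slope_mut)
        assert slope_mut < slope_wt
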