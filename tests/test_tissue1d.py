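"""1D strand tests: diffusion, conservation, CV, thresholds, vulnerability."""

import numpy as np
import pytest

from atriacal import tissue1d as t1
from atriacal.cell_model import ConfigurationError
from atriacal.fixtures import make_junction_strand
from atriacal._sim import StimEvent


class TestConfig:
    def test_cfl_violation_rejected_before_run(self):
        cfg = t1.StrandConfig()
        with pytest.raises(ConfigurationError):
            t1.run_strand(cfg, [], 10.0, dt=0.2)  # dx^2/(2D) ~ 0.149 ms

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            t1.StrandConfig(n_nodes=2)
        with pytest.raises(ConfigurationError):
            t1.StrandConfig(dx=0.0)
        with pytest.raises(ConfigurationError):
            t1.StrandConfig(regions=("RA", "LA"))  # neither 1 nor n labels


class TestDiffusion:
    def test_decoupled_limit_keeps_neighbours_at_rest(self):
        cfg = t1.StrandConfig(n_nodes=20, D=0.0)
        res = t1.run_strand(cfg, [StimEvent(5.0, 80.0, 2.0, 0, 0)], 60.0,
                            rec_every=100)
        assert res.act_counts[0] == 1          # stimulated node fires
        assert np.all(res.act_counts[1:] == 0)  # neighbours stay at rest
        assert np.all(res.vrec[-1, 1:] < -70.0)

    def test_uniform_resting_strand_is_conserved(self):
        """Zero-flux ends: an unstimulated uniform strand stays uniform."""
        cfg = t1.StrandConfig(n_nodes=30)
        res = t1.run_strand(cfg, [], 200.0, rec_every=10)
        spread = res.vrec.max(axis=1) - res.vrec.min(axis=1)
        assert np.max(spread) < 1e-10


class TestConductionVelocity:
    def test_synthetic_travelling_wave_speed_recovered_exactly(self):
        cfg = t1.StrandConfig()
        v_mm_ms = 0.5
        rec_dt = 0.5
        t = np.arange(0.0, 120.0, rec_dt)
        x = cfg.dx * np.arange(cfg.n_nodes)
        # sharp upstroke travelling at v: V = -80 + 100*H(v t - x)
        vm = -80.0 + 100.0 / (1.0 + np.exp(-(v_mm_ms * t[:, None]
                                             - x[None, :]) / 0.05))
        cv = t1.cv_from_vm(vm, rec_dt, cfg)
        assert cv == pytest.approx(v_mm_ms * 100.0, rel=1e-3)

    def test_no_activation_flags_zero(self):
        cfg = t1.StrandConfig()
        vm = np.full((100, cfg.n_nodes), -80.0)
        assert t1.cv_from_vm(vm, 0.5, cfg) == 0.0

    def test_cv_converges_under_grid_refinement(self):
        """Halving dx (same dt) changes CV by < 5 %."""
        cv = {}
        for dx, n in ((0.25, 100), (0.125, 200)):
            cfg = t1.StrandConfig(n_nodes=n, dx=dx)
            # measurement nodes at the same physical positions
            node_a, node_b = int(6.0 / dx), int(18.5 / dx)
            res, _ = t1.condition_strand(cfg, 1000.0, n_beats=2, dt=0.005)
            cv[dx] = t1.measure_cv(res, cfg, after=0.0, node_a=node_a,
                                   node_b=node_b)
        assert cv[0.125] == pytest.approx(cv[0.25], rel=0.05)


class TestWavelengthAndThreshold:
    def test_wavelength_is_product_of_cv_and_erp(self, strand_bundle):
        b = strand_bundle[0.0]
        assert b["WL_mm"] == pytest.approx(
            b["CV_cm_per_s"] / 100.0 * b["ERP_ms"], rel=1e-12)
        assert 55.0 < b["CV_cm_per_s"] < 85.0
        assert 150.0 < b["WL_mm"] < 260.0  # physiological WT range

    def test_wavelength_shrinks_monotonically_with_deficiency(self, strand_bundle):
        wls = [strand_bundle[f]["WL_mm"] for f in (0.0, 0.5, 1.0)]
        assert wls[0] > wls[1] > wls[2]

    def test_ext_bisection_matches_linear_scan(self, strand_bundle):
        b = strand_bundle[0.0]
        ext_b = t1.excitation_threshold(b["cfg"], 700.0, state=b["state"],
                                        resolution=2.0)
        ext_s = t1.excitation_threshold(b["cfg"], 700.0, state=b["state"],
                                        resolution=2.0, mode="scan")
        assert abs(ext_b - ext_s) <= 2.0

    def test_deep_refractoriness_returns_capped_value(self, strand_bundle):
        b = strand_bundle[0.0]
        assert t1.excitation_threshold(b["cfg"], 60.0,
                                       state=b["state"]) == t1.EXT_CAP

    def test_late_si_equals_lone_diastolic_threshold(self, strand_bundle):
        """Far beyond ERP the S2 threshold equals a lone-stimulus threshold."""
        b = strand_bundle[0.0]
        late = t1.excitation_threshold(b["cfg"], 900.0, state=b["state"])
        Y, eff = t1.strand_states(b["cfg"])
        lone = t1.excitation_threshold(b["cfg"], 900.0, state=(Y, eff))
        assert abs(late - lone) <= 2.0

    def test_critical_si_on_synthetic_step_profile(self, monkeypatch):
        """A synthetic step EXT(SI) yields exactly the step location."""
        cfg = t1.StrandConfig()
        monkeypatch.setattr(t1, "condition_strand",
                            lambda *a, **k: (None, (None, None)))
        monkeypatch.setattr(
            t1, "excitation_threshold",
            lambda cfg, si, state=None, dt=None, **k:
                30.0 if si >= 283.0 else 450.0)
        si, ext = t1.critical_si(cfg)
        assert si == pytest.approx(282.0)
        assert ext == pytest.approx(450.0)


class TestVulnerableWindow:
    def test_symmetric_homogeneous_strand_has_no_window(self):
        """With both ends paced (colliding S1 waves) the recovery profile is
        symmetric about the mid-strand S2 site, so no S2 timing produces
        unidirectional block."""
        cfg = t1.StrandConfig(s2_lo=47, s2_hi=52)
        sites = [(0, 1), (cfg.n_nodes - 2, cfg.n_nodes - 1)]
        _, state = t1.condition_strand(cfg, stim_sites=sites)
        labels = {si: t1.classify_s2(cfg, state, float(si), stim_sites=sites)
                  for si in range(200, 340, 4)}
        assert "unidirectional_block" not in labels.values()
        assert "bidirectional_conduction" in labels.values()
        assert "bidirectional_block" in labels.values()

    def test_junction_strand_has_finite_window(self, vw_bundle):
        vw = vw_bundle[("CT_PM", 0.0)]
        assert vw.width > 0.5
        assert any(v == "unidirectional_block" for v in vw.outcomes.values())
        assert any(v == "bidirectional_conduction" for v in vw.outcomes.values())

    def test_vw_edges_match_fine_linear_scan(self):
        """Bisected edges agree with a 0.5-ms linear scan near the edges."""
        cfg = make_junction_strand("CT_PM")
        vw = t1.vulnerable_window(cfg, resolution=0.5)
        _, state = t1.condition_strand(cfg)
        for edge in (vw.lower, vw.upper):
            labels = {d: t1.classify_s2(cfg, state, edge + d)
                      for d in (-0.75, 0.75)}
            assert len(set(labels.values())) == 2  # the edge separates classes
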