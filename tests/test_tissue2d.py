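"""2D operator tests on analytic fields: tips, meander, DF, pseudo-ECG."""

import numpy as np
import pytest

from atriacal import tissue2d as t2
from atriacal.fixtures import make_analytic_rotor


@pytest.fixture(scope="module")
def rotor():
    return make_analytic_rotor(ny=60, nx=60, n_frames=300)


class TestTipTracking:
    def test_single_rotor_core_found_within_one_cell(self, rotor):
        traj = t2.track_tips(rotor["frames"], rotor["frame_dt"], rotor["dx"])
        assert len(traj.xy) > 250  # tracked through nearly every frame
        err = np.hypot(*(traj.xy - np.array(rotor["core"])).T)
        assert np.max(err) <= np.sqrt(2.0) * rotor["dx"]

    def test_counter_rotating_pair_has_opposite_chirality(self):
        a = make_analytic_rotor(ny=40, nx=80, core=(5.0, 5.0), n_frames=60,
                                chirality=1)
        b = make_analytic_rotor(ny=40, nx=80, core=(15.0, 5.0), n_frames=60,
                                chirality=-1)
        # merge the two half-planes along x
        frames = np.concatenate([a["frames"][:, :, :40],
                                 b["frames"][:, :, 40:]], axis=2)
        theta = t2.phase_field(frames, 1.0)
        pos, charge = t2._frame_singularities(theta[30], 0.25)
        assert len(pos) >= 2
        left = charge[pos[:, 0] < 10.0]
        right = charge[pos[:, 0] >= 10.0]
        assert set(np.sign(left)) == {1.0} or set(np.sign(left)) == {-1.0}
        assert np.sign(left[0]) == -np.sign(right[0])

    def test_topological_charge_is_conserved_frame_to_frame(self, rotor):
        """A lone rotor far from boundaries keeps total charge +-1."""
        theta = t2.phase_field(rotor["frames"], rotor["frame_dt"])
        charges = []
        for k in range(0, theta.shape[0], 10):
            _, c = t2._frame_singularities(theta[k], rotor["dx"])
            charges.append(int(np.sum(c)))
        assert len(set(charges)) == 1 and abs(charges[0]) == 1

    def test_stationary_core_sweeps_no_area(self, rotor):
        traj = t2.track_tips(rotor["frames"], rotor["frame_dt"], rotor["dx"])
        assert t2.meander_area(traj) < 0.01  # cm^2; sub-grid jitter only


class TestMeanderArea:
    def _traj(self, xy):
        xy = np.asarray(xy, float)
        return t2.TipTrajectory(np.arange(len(xy), dtype=float), xy,
                                np.ones(len(xy)))

    def test_circle_area_matches_pi_r_squared(self):
        ang = np.linspace(0.0, 2.0 * np.pi, 400, endpoint=False)
        r = 12.0  # mm
        xy = np.stack([20 + r * np.cos(ang), 20 + r * np.sin(ang)], axis=1)
        area = t2.meander_area(self._traj(xy))
        assert area == pytest.approx(np.pi * r * r / 100.0, rel=0.01)

    def test_area_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0.0, 30.0, (100, 2))
        a0 = t2.meander_area(self._traj(xy))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        a1 = t2.meander_area(self._traj(xy @ rot.T + np.array([5.0, -3.0])))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_degenerate_trajectories_have_zero_area(self):
        assert t2.meander_area(self._traj([[0, 0], [1, 1]])) == 0.0
        collinear = [[x, 2.0 * x] for x in np.linspace(0, 5, 17)]
        assert t2.meander_area(self._traj(collinear)) == 0.0


class TestDominantFrequency:
    def test_pure_sinusoid_recovered_within_one_bin(self):
        dt = 2.0  # ms
        t = np.arange(0, 6000.0, dt)
        sig = 3.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        df = t2.dominant_frequency(sig, dt)
        assert df == pytest.approx(5.0, abs=1000.0 / (t.size * dt - 1000.0) + 1e-9)

    def test_largest_amplitude_component_wins(self):
        dt = 2.0
        t = np.arange(0, 6000.0, dt)
        sig = (1.0 * np.sin(2 * np.pi * 3.0 * t / 1000.0)
               + 2.0 * np.sin(2 * np.pi * 7.0 * t / 1000.0))
        assert t2.dominant_frequency(sig, dt) == pytest.approx(7.0, abs=0.3)

    def test_flat_signal_is_flagged(self):
        assert np.isnan(t2.dominant_frequency(np.zeros(4000), 1.0))


class TestPseudoEcg:
    def test_uniform_field_gives_exactly_zero(self):
        movie = np.full((3, 30, 30), -20.0, dtype=np.float32)
        phi = t2.pseudo_ecg(movie, 0.25, (3.75, 3.75, 10.0))
        assert np.allclose(phi, 0.0, atol=1e-12)

    def test_far_field_scales_as_inverse_square_distance(self):
        """Doubling the electrode distance quarters the dipole-layer signal."""
        ny = nx = 40
        dx = 0.25
        x = dx * np.arange(nx)
        vm = np.tile(100.0 / (1.0 + np.exp(-(x - 5.0) / 0.5)), (ny, 1))
        movie = vm[None, :, :].astype(np.float32)
        cy = (ny - 1) * dx / 2.0
        # electrode along the dipole axis (x), where the far field ~ 1/r^2
        d1, d2 = 60.0, 120.0
        phi1 = t2.pseudo_ecg(movie, dx, (5.0 + d1, cy, 2.0))[0]
        phi2 = t2.pseudo_ecg(movie, dx, (5.0 + d2, cy, 2.0))[0]
        assert phi1 / phi2 == pytest.approx((d2 / d1) ** 2, rel=0.05)

    def test_electrode_on_tissue_rejected(self):
        movie = np.zeros((1, 10, 10), dtype=np.float32)
        with pytest.raises(Exception):
            t2.pseudo_ecg(movie, 0.25, (1.0, 1.0, 0.0))


class TestLifespan:
    def _result(self, frames, frame_dt=1.0, s2=10.0):
        cfg = t2.SheetConfig(nx=frames.shape[2], ny=frames.shape[1],
                             duration=float(frames.shape[0]), dt=0.01)
        return t2.SheetResult(frames.astype(np.float32), frame_dt,
                              frames.mean(axis=(1, 2)), s2, cfg)

    def test_lifespan_of_clearing_wave(self):
        frames = np.full((100, 12, 12), -80.0)
        frames[10:40, 5, 5] = 0.0  # activity until frame 39
        res = self._result(frames, s2=10.0)
        assert t2.reentry_lifespan(res) == pytest.approx(29.0, abs=1.01)
        assert not t2.is_sustained(res)

    def test_sustained_activity_capped_at_duration(self):
        frames = np.full((100, 12, 12), -80.0)
        frames[10:, 3, 3] = 0.0
        res = self._result(frames, s2=10.0)
        assert t2.is_sustained(res)
        assert t2.reentry_lifespan(res) == pytest.approx(89.0, abs=1.01)


class TestIntegratedVm:
    def test_resting_sheet_mean_equals_rmp(self):
        frames = np.full((5, 12, 12), -81.2, dtype=np.float32)
        cfg = t2.SheetConfig(nx=12, ny=12, duration=5.0, dt=0.01)
        res = t2.SheetResult(frames, 1.0, frames.mean(axis=(1, 2)), 0.0, cfg)
        t, ivm = t2.integrated_vm(res)
        assert np.allclose(ivm, -81.2, atol=1e-5)
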