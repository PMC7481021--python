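import numpy as np
import pytest

from swimbeam import config
from swimbeam.kinematics import (
    compute_deformation_state,
    fictitious_loads,
    fit_deformation_plane,
    make_travelling_wave,
)


class TestDeformationPlane:
    def test_coplanar_points_recovered_exactly(self):
        rng = np.random.default_rng(1)
        n = np.array([1.0, 2.0, -0.5])
        n /= np.linalg.norm(n)
        u = np.array([2.0, -1.0, 0.0]); u -= (u @ n) * n; u /= np.linalg.norm(u)
        v = np.cross(n, u)
        pts = (rng.normal(size=(500, 1)) * u + rng.normal(size=(500, 1)) * v
               + np.array([3.0, 1.0, 2.0]))
        origin, axes, normal, proj, rms = fit_deformation_plane(pts)
        assert rms < 1e-12
        assert np.isclose(abs(normal @ n), 1.0, atol=1e-10)

    def test_noisy_plane_normal_within_two_degrees(self):
        """Monte-Carlo: isotropic noise of 1 % of the extent leaves the
        recovered normal within 2 degrees of the generating normal."""
        rng = np.random.default_rng(42)
        n = np.array([0.0, 0.0, 1.0])
        pts = np.column_stack([rng.uniform(-1, 1, 2000),
                               rng.uniform(-1, 1, 2000),
                               np.zeros(2000)])
        pts += rng.normal(0, 0.01 * 2.0, size=pts.shape)
        _, _, normal, _, _ = fit_deformation_plane(pts)
        angle = np.degrees(np.arccos(min(1.0, abs(normal @ n))))
        assert angle < 2.0

    def test_degenerate_point_set_rejected(self):
        with pytest.raises(ValueError):
            fit_deformation_plane(np.zeros((50, 3)))
        line = np.outer(np.linspace(0, 1, 50), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            fit_deformation_plane(line)


class TestTravellingWave:
    def test_zero_envelope_gives_straight_body(self, body):
        kin = make_travelling_wave(np.zeros_like(body.s), 50.0, 4e-3,
                                   0.05, body, n_t=25)
        assert np.allclose(kin.kappa, 0.0, atol=1e-9)
        assert np.allclose(kin.y, 0.0, atol=1e-12)

    def test_arc_length_preserved(self, body):
        env = 400.0 * (body.s / body.length) ** 2
        kin = make_travelling_wave(env, 50.0, 4e-3, 0.04, body, n_t=81)
        assert np.allclose(kin.arc_length(), body.length, rtol=1e-9)

    def test_tail_beat_period_from_frequency(self, body):
        """At 50 Hz the lateral tail-tip extrema are 10 ms apart."""
        from scipy.signal import find_peaks

        env = 300.0 * (body.s / body.length) ** 2
        kin = make_travelling_wave(env, 50.0, 4e-3, 0.1, body, n_t=501)
        tip = kin.eta[-1]
        pk, _ = find_peaks(tip)
        gaps = np.diff(kin.t[pk])
        assert np.allclose(gaps, 0.02, atol=2e-4)  # full period between maxima

    def test_negative_envelope_rejected(self, body):
        with pytest.raises(ValueError):
            make_travelling_wave(-np.ones_like(body.s), 50.0, 4e-3, 0.05, body)

    def test_curvature_originates_behind_the_head(self, body):
        env = np.full_like(body.s, 200.0)
        kin = make_travelling_wave(env, 50.0, 4e-3, 0.04, body, n_t=41)
        u = body.s / body.length
        head = np.abs(kin.kappa[u < 0.05]).max()
        trunk = np.abs(kin.kappa[u > 0.4]).max()
        assert head < 0.05 * trunk


class TestDeformationState:
    def test_rigid_translation(self):
        s = np.linspace(0, 4e-3, 31)
        t = np.linspace(0, 0.1, 11)
        x = s[:, None] + 0.05 * t[None, :]
        y = np.zeros_like(x) + 0.02 * t[None, :]
        kin = compute_deformation_state(x, y, t, s)
        assert np.allclose(kin.theta, 0.0, atol=1e-10)
        assert np.allclose(kin.kappa, 0.0, atol=1e-7)
        assert np.allclose(kin.theta_tt, 0.0, atol=1e-6)

    def test_static_circular_arc(self):
        R = 0.01
        s = np.linspace(0, 3e-3, 61)
        t = np.linspace(0, 1, 9)
        ang = s / R
        x = np.tile((R * np.sin(ang))[:, None], (1, 9))
        y = np.tile((R * (1 - np.cos(ang)))[:, None], (1, 9))
        kin = compute_deformation_state(x, y, t, s)
        assert np.allclose(kin.kappa * R, 1.0, rtol=1e-6)

    def test_polynomial_motion_derivatives_exact(self):
        """Motion polynomial in t of degree <= 5: spline time derivatives
        equal the symbolic ones.  The anterior trunk is kept straight so the
        head frame stays fixed and eta coincides with y."""
        s = np.linspace(0, 4e-3, 31)
        t = np.linspace(0, 0.1, 15)
        u = s / s[-1]
        h = np.clip(u - 0.2, 0.0, None) ** 3
        g = t**5 - 0.3 * t**3
        c = 1e-2
        y = c * np.outer(h, g)
        x = np.tile(s[:, None], (1, t.size))
        kin = compute_deformation_state(x, y, t, s)
        eta_tt_exact = c * np.outer(h, 20 * t**3 - 1.8 * t)
        scale = np.abs(eta_tt_exact).max()
        assert np.allclose(kin.eta, y, atol=1e-4 * np.abs(y).max())
        assert np.allclose(kin.eta_tt, eta_tt_exact, atol=1e-4 * scale)

    def test_nan_rejected_with_location(self):
        s = np.linspace(0, 1e-3, 11)
        t = np.linspace(0, 1, 11)
        x = np.tile(s[:, None], (1, 11))
        y = np.zeros_like(x)
        y[3, 7] = np.nan
        with pytest.raises(ValueError, match="s index 3, t index 7"):
            compute_deformation_state(x, y, t, s)

    def test_non_monotone_grid_rejected(self):
        s = np.linspace(0, 1e-3, 11)
        t = np.r_[np.linspace(0, 1, 10), 0.5]
        x = np.tile(s[:, None], (1, 11))
        with pytest.raises(ValueError):
            compute_deformation_state(x, np.zeros_like(x), t, s)


class TestFrameInvariance:
    @staticmethod
    def _wave(body, n_t=41):
        env = 300.0 * (body.s / body.length) ** 2
        return make_travelling_wave(env, 50.0, 4e-3, 0.04, body, n_t=n_t)

    def test_galilean_invariance(self, body):
        """A constant lab-frame velocity leaves curvature, deformation
        angles and fictitious loads unchanged."""
        kin = self._wave(body)
        vx, vy = 0.13, -0.07
        x2 = kin.x + vx * kin.t[None, :]
        y2 = kin.y + vy * kin.t[None, :]
        kin2 = compute_deformation_state(x2, y2, kin.t, kin.s)
        assert np.allclose(kin2.kappa, kin.kappa, atol=1e-6)
        assert np.allclose(kin2.theta, kin.theta, atol=1e-9)
        f1 = fictitious_loads(kin.frame, kin, body)
        f2 = fictitious_loads(kin2.frame, kin2, body)
        scale = max(np.abs(f1.f_y).max(), 1e-12)
        assert np.allclose(f2.f_x, f1.f_x, atol=1e-6 * scale)
        assert np.allclose(f2.f_y, f1.f_y, atol=1e-6 * scale)

    def test_mirror_symmetry(self, body):
        """Reflecting y -> -y negates theta, kappa, eta and the lateral
        fictitious load."""
        kin = self._wave(body)
        kin2 = compute_deformation_state(kin.x, -kin.y, kin.t, kin.s)
        assert np.allclose(kin2.theta, -kin.theta, atol=1e-10)
        assert np.allclose(kin2.kappa, -kin.kappa, atol=1e-8)
        assert np.allclose(kin2.eta, -kin.eta, atol=1e-12)
        f1 = fictitious_loads(kin.frame, kin, body)
        f2 = fictitious_loads(kin2.frame, kin2, body)
        scale = max(np.abs(f1.f_y).max(), 1e-15)
        assert np.allclose(f2.f_y, -f1.f_y, atol=1e-9 * scale)
        assert np.allclose(f2.f_x, f1.f_x, atol=1e-9 * scale)


class TestFictitiousLoads:
    def test_inertial_frame_zero_loads(self, body):
        kin = TestFrameInvariance._wave(body)
        frame = kin.frame
        frame.a0 = np.zeros_like(frame.a0)
        frame.omega = np.zeros_like(frame.omega)
        frame.omega_dot = np.zeros_like(frame.omega_dot)
        loads = fictitious_loads(frame, kin, body)
        assert np.allclose(loads.f_x, 0) and np.allclose(loads.f_y, 0)
        assert np.allclose(loads.m_z, 0)

    def test_pure_frame_acceleration_straight_body(self, body):
        s = body.s
        t = np.linspace(0, 0.1, 11)
        a = 2.5
        x = s[:, None] + 0.5 * a * t[None, :] ** 2
        y = np.zeros_like(x)
        kin = compute_deformation_state(x, y, t, s)
        loads = fictitious_loads(kin.frame, kin, body)
        assert np.allclose(loads.f_x, -body.mu[:, None] * a, atol=1e-8)
        assert np.allclose(loads.f_y, 0.0, atol=1e-8)
        assert np.allclose(loads.m_z, 0.0, atol=1e-12)

    def test_rotating_frame_recovers_lab_acceleration(self, body):
        """Two-frame oracle: for a body rotating rigidly about the head,
        head-frame inertia plus fictitious terms reproduce the lab-frame
        acceleration of every axis point (here: zero net lateral force on a
        point at rest in the rotating frame is *not* expected; instead the
        identity rho A a_rel = R(-phi) rho A a_lab + f_fict must hold)."""
        s = body.s
        t = np.linspace(0, 0.05, 31)
        Om = 12.0  # rad/s, constant rotation about the snout
        ang = Om * t
        x = np.outer(s, np.cos(ang))
        y = np.outer(s, np.sin(ang))
        kin = compute_deformation_state(x, y, t, s)
        f = fictitious_loads(kin.frame, kin, body)
        # lab acceleration of a point at radius s: centripetal, magnitude
        # s Om^2 toward the origin; head-frame x axis tracks the body
        a_lab_x = -s[:, None] * Om**2 * np.ones_like(t)[None, :]
        lhs = body.mu[:, None] * kin.xi_tt
        rhs = body.mu[:, None] * a_lab_x + f.f_x
        scale = np.abs(body.mu[:, None] * a_lab_x).max()
        assert np.allclose(lhs[:, 3:-3], rhs[:, 3:-3], atol=1e-6 * scale)
        lhs_y = body.mu[:, None] * kin.eta_tt
        rhs_y = f.f_y
        assert np.allclose(lhs_y[:, 3:-3], rhs_y[:, 3:-3], atol=1e-6 * scale)
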