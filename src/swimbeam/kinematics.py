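"""Centreline kinematics in the deformation plane and the head frame.

The swimmer deforms in a single plane.  Motion is described by the
positions of the central axis on a rectangular (s, t) grid in an inertial
frame attached to that plane.  For inverse dynamics the equations are
written in a non-inertial frame attached to the head (origin at the snout,
x axis along the mean anterior tangent); the head-frame displacements
``xi``, ``eta`` are measured relative to the straight, undeformed
configuration, and the frame's acceleration and rotation enter the
dynamics through fictitious forces.

Sign conventions: s runs snout to tail; the head-frame y axis points to
the fish's left; the tangent angle theta is measured counter-clockwise
from the head-frame x axis; curvature kappa = dtheta/ds, so bending that
is concave toward the fish's left is positive.

All derivative evaluation goes through quintic-spline representations,
never raw differences, so irregular time grids are handled and the
derivatives are the analytic derivatives of one consistent interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .loads import LoadDistribution
from .splines import time_derivatives, time_spline

__all__ = [
    "CentrelineKinematics",
    "FrameMotion",
    "fit_deformation_plane",
    "make_travelling_wave",
    "compute_deformation_state",
    "fictitious_loads",
]


@dataclass
class FrameMotion:
    """Motion of the head-attached frame relative to the inertial plane frame."""

    t: np.ndarray
    origin: np.ndarray       # (2, n_t) plane-frame position of the frame origin
    angle: np.ndarray        # (n_t,) frame orientation (rad, unwrapped)
    a0: np.ndarray           # (2, n_t) origin acceleration, head-frame components
    omega: np.ndarray        # (n_t,) angular velocity (rad/s)
    omega_dot: np.ndarray    # (n_t,) angular acceleration (rad/s^2)


@dataclass
class CentrelineKinematics:
    """Planar centreline motion with head-frame deformation fields.

    Scalar fields have shape (n_s, n_t); time is the last axis.
    """

    t: np.ndarray
    s: np.ndarray
    x: np.ndarray            # plane-frame positions
    y: np.ndarray
    xi: np.ndarray           # head-frame displacement in x (rel. to straight body)
    eta: np.ndarray          # head-frame displacement in y
    theta: np.ndarray        # head-frame tangent angle (unwrapped)
    kappa: np.ndarray        # dtheta/ds
    xi_t: np.ndarray
    xi_tt: np.ndarray
    eta_t: np.ndarray
    eta_tt: np.ndarray
    theta_t: np.ndarray
    theta_tt: np.ndarray
    kappa_t: np.ndarray
    body_angle: np.ndarray   # (n_t,) tangent angle averaged along the body (plane frame)
    frame: FrameMotion
    stretch: np.ndarray = field(default=None)  # |dr/ds| (1 for inextensible)

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def arc_length(self) -> np.ndarray:
        """Centreline length per time sample (trapezoid of the local stretch)."""
        return np.trapezoid(self.stretch, self.s, axis=0)

    def lab_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Plane-frame velocity of every axis point (spline time derivative)."""
        (vx,) = time_derivatives(self.t, self.x, orders=(1,))
        (vy,) = time_derivatives(self.t, self.y, orders=(1,))
        return vx, vy

    def lab_velocity_head_components(self) -> tuple[np.ndarray, np.ndarray]:
        """Plane-frame velocity expressed in head-frame axes."""
        vx, vy = self.lab_velocity()
        c = np.cos(self.frame.angle)[None, :]
        sn = np.sin(self.frame.angle)[None, :]
        return c * vx + sn * vy, -sn * vx + c * vy

    def theta_lab(self) -> np.ndarray:
        return self.theta + self.frame.angle[None, :]

    def com_trajectory(self, body) -> np.ndarray:
        """Centre-of-mass plane-frame trajectory, shape (2, n_t)."""
        w = body.mu
        norm = np.trapezoid(w, self.s)
        cx = np.trapezoid(w[:, None] * self.x, self.s, axis=0) / norm
        cy = np.trapezoid(w[:, None] * self.y, self.s, axis=0) / norm
        return np.stack([cx, cy])


def fit_deformation_plane(points: np.ndarray):
    """Total-least-squares plane through a 3-D point cloud.

    ``points`` has shape (..., 3).  Returns ``(origin, axes, normal,
    projected, rms)`` where ``axes`` is a (2, 3) array of orthonormal
    in-plane directions, ``projected`` are the in-plane coordinates with the
    trailing axis of length 2, and ``rms`` is the out-of-plane residual RMS.
    """
    pts = np.asarray(points, float)
    flat = pts.reshape(-1, 3)
    if flat.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    origin = flat.mean(axis=0)
    centred = flat - origin
    # SVD of the centred cloud: the plane minimising total squared orthogonal
    # distance is spanned by the two leading right singular vectors
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise ValueError("point set is collinear or degenerate; no unique plane")
    axes = vt[:2]
    normal = vt[2]
    projected = (centred @ axes.T).reshape(pts.shape[:-1] + (2,))
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return origin, axes, normal, projected, rms


def make_travelling_wave(
    curvature_amplitude,
    frequency: float,
    body_wavelength: float,
    duration: float,
    body,
    n_t: int = 201,
    head_taper: float = 0.25,
) -> CentrelineKinematics:
    """Generate inextensible travelling-wave kinematics with the head fixed.

    kappa(s, t) = envelope(s) * sin(2 pi (f t - s / lambda)), with the
    envelope smoothly tapered to zero over the anterior ``head_taper``
    fraction of the body so that curvature waves originate behind the stiff
    head.  Positions are obtained by arc-length-preserving integration of
    the unit tangent, so the centreline length is exactly the body length.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    s = body.s
    L = body.length
    env = curvature_amplitude(s) if callable(curvature_amplitude) else (
        np.asarray(curvature_amplitude, float))
    if np.any(env < 0):
        raise ValueError("curvature amplitude envelope must be non-negative")
    u = s / L
    taper = np.ones_like(u)
    if head_taper > 0:
        m = u < head_taper
        taper[m] = 0.5 - 0.5 * np.cos(np.pi * u[m] / head_taper)
    env = env * taper
    t = np.linspace(0.0, duration, n_t)
    phase = 2 * np.pi * (frequency * t[None, :] - s[:, None] / body_wavelength)
    kappa = env[:, None] * np.sin(phase)
    # theta by s-integration of the curvature spline (exact antiderivative)
    theta = np.empty_like(kappa)
    x = np.empty_like(kappa)
    y = np.empty_like(kappa)
    for j in range(t.size):
        kspl = make_interp_spline(s, kappa[:, j], k=5)
        theta[:, j] = kspl.antiderivative()(s)
        tx = make_interp_spline(s, np.cos(theta[:, j]), k=5)
        ty = make_interp_spline(s, np.sin(theta[:, j]), k=5)
        x[:, j] = tx.antiderivative()(s)
        y[:, j] = ty.antiderivative()(s)
    return compute_deformation_state(x, y, t, s)


def compute_deformation_state(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    s: np.ndarray,
    head_fraction: float = 0.1,
) -> CentrelineKinematics:
    """Full deformation state (angles, curvature, head frame, all time
    derivatives) from plane-frame positions on a rectangular (s, t) grid.

    The head frame is anchored at s = 0 with orientation given by the mean
    plane-frame tangent angle over the anterior ``head_fraction`` of the
    body; the anchoring convention is configurable and the reconstructed
    bending moment is insensitive to it (the fictitious loads compensate).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    for name, g in (("t", t), ("s", s)):
        if np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} grid must be strictly increasing")
    if x.shape != (s.size, t.size) or y.shape != (s.size, t.size):
        raise ValueError("positions must be sampled on the rectangular (s, t) grid")
    if s.size < 7 or t.size < 7:
        raise ValueError("need at least 7 samples per axis")
    for name, arr in (("x", x), ("y", y)):
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(f"non-finite {name} at s index {i}, t index {j}")

    xs = make_interp_spline(s, x, k=5, axis=0).derivative()(s)
    ys = make_interp_spline(s, y, k=5, axis=0).derivative()(s)
    stretch = np.hypot(xs, ys)
    theta_lab = np.arctan2(ys, xs)
    theta_lab = np.unwrap(theta_lab, axis=0)
    # continuity along t, seeded at the head
    head = theta_lab[0]
    shift = np.round(np.diff(head) / (2 * np.pi)).cumsum()
    theta_lab[:, 1:] -= 2 * np.pi * np.concatenate([[0], shift])[1:][None, :]

    body_angle = theta_lab.mean(axis=0)

    n_head = max(2, int(np.ceil(head_fraction * s.size)))
    phi = theta_lab[:n_head].mean(axis=0)
    px, py = x[0], y[0]

    c, sn = np.cos(phi)[None, :], np.sin(phi)[None, :]
    dx, dy = x - px[None, :], y - py[None, :]
    xi = c * dx + sn * dy - s[:, None]
    eta = -sn * dx + c * dy
    theta = theta_lab - phi[None, :]
    kappa = make_interp_spline(s, theta, k=5, axis=0).derivative()(s)

    xi_t, xi_tt = time_derivatives(t, xi)
    eta_t, eta_tt = time_derivatives(t, eta)
    theta_t, theta_tt = time_derivatives(t, theta)
    (kappa_t,) = time_derivatives(t, kappa, orders=(1,))

    omega, omega_dot = time_derivatives(t, phi)
    _, ax = time_derivatives(t, px)
    _, ay = time_derivatives(t, py)
    a0 = np.stack([np.cos(phi) * ax + np.sin(phi) * ay,
                   -np.sin(phi) * ax + np.cos(phi) * ay])
    frame = FrameMotion(t=t, origin=np.stack([px, py]), angle=phi,
                        a0=a0, omega=omega, omega_dot=omega_dot)

    return CentrelineKinematics(
        t=t, s=s, x=x, y=y, xi=xi, eta=eta, theta=theta, kappa=kappa,
        xi_t=xi_t, xi_tt=xi_tt, eta_t=eta_t, eta_tt=eta_tt,
        theta_t=theta_t, theta_tt=theta_tt, kappa_t=kappa_t,
        body_angle=body_angle, frame=frame, stretch=stretch,
    )


def fictitious_loads(frame: FrameMotion, kin: CentrelineKinematics,
                     body) -> LoadDistribution:
    """Inertial pseudo-loads of the accelerating, rotating head frame.

    Per unit length (head-frame components, z the plane normal):

        f_fict = -mu(s) [a0 + Omega_dot z x r - Omega^2 r + 2 Omega z x v_rel]
        m_fict = -rho_fish I(s) Omega_dot

    with r the head-frame position of the axis point and v_rel its
    head-frame velocity.
    """
    if not np.array_equal(frame.t, kin.t):
        raise ValueError("frame and kinematics do not share a time grid")
    mu = body.mu[:, None]
    rx = kin.s[:, None] + kin.xi
    ry = kin.eta
    Om = frame.omega[None, :]
    Omd = frame.omega_dot[None, :]
    a0x = frame.a0[0][None, :]
    a0y = frame.a0[1][None, :]
    # z x (a, b) = (-b, a)
    f_x = -mu * (a0x - Omd * ry - Om**2 * rx - 2 * Om * kin.eta_t)
    f_y = -mu * (a0y + Omd * rx - Om**2 * ry + 2 * Om * kin.xi_t)
    m_z = -body.rho_fish * body.second_moment[:, None] * np.broadcast_to(
        Omd, f_x.shape).copy()
    return LoadDistribution(s=kin.s, t=kin.t, f_x=f_x, f_y=f_y, m_z=m_z,
                            provenance="fictitious")
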