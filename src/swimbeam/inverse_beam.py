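"""Reconstruction of internal forces and moments by spline collocation.

Core method of the toolkit.  At every time sample the normal force N(s),
shear force Q(s) and bending moment M(s) are represented by quintic
splines with uniformly spaced control points, constrained to vanish at
both ends (free-end boundary conditions hold exactly by construction).
The control values are found by minimising the squared sum of the
normalised residuals of the planar large-amplitude beam equations of
motion, written in the head-attached frame,

    r1 = rho A xi_tt   + d/ds(N cos th) - d/ds(Q sin th) - f_x
    r2 = rho A eta_tt  + d/ds(N sin th) + d/ds(Q cos th) - f_y
    r3 = rho I th_tt   + dM/ds + Q - m_z

with f and m_z the total external loads (fluid + fictitious; distributed
muscle couples are zero — N, Q, M are the net internal stress resultants,
combining muscle and passive-tissue contributions).  The equations contain
no time derivatives of the unknowns, so each sample is solved
independently, warm-started from the previous sample.  The residuals are
linear in the control values; the damped least-squares
(Levenberg–Marquardt) solve therefore converges in a handful of
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .splines import SplineBasis

__all__ = [
    "InternalState",
    "build_spline_basis",
    "assemble_residuals",
    "reconstruct_internal",
    "reconstruction_error",
    "characteristic_scales",
]


def build_spline_basis(n_c: int, s_grid: np.ndarray) -> SplineBasis:
    """Quintic-spline basis with ``n_c`` uniform control points on the
    collocation grid; carries both the unconstrained and the end-vanishing
    constrained evaluation/derivative operators."""
    return SplineBasis(n_c, s_grid)


@dataclass
class InternalState:
    """Spline-represented N(s,t), Q(s,t), M(s,t) with free ends.

    ``N``, ``Q``, ``M`` are the fields evaluated on the collocation grid;
    the raw control values (constrained basis) are kept for re-evaluation.
    """

    s: np.ndarray
    t: np.ndarray
    N: np.ndarray
    Q: np.ndarray
    M: np.ndarray
    control: np.ndarray           # (3 * n_free, n_t)
    basis: SplineBasis
    residual_norm: np.ndarray     # normalised residual RMS per sample
    iterations: np.ndarray
    flagged: np.ndarray = field(default=None)  # non-converged samples

    def interpolate_flagged(self) -> None:
        """Replace flagged samples by linear interpolation of their
        neighbours' control values (explicit user request only)."""
        bad = np.flatnonzero(self.flagged)
        good = np.flatnonzero(~self.flagged)
        if bad.size == 0:
            return
        if good.size == 0:
            raise ValueError("all samples are flagged; nothing to interpolate from")
        for row in range(self.control.shape[0]):
            self.control[row, bad] = np.interp(self.t[bad], self.t[good],
                                               self.control[row, good])
        n_free = self.basis.n_free
        E = self.basis.eval_op_constrained
        self.N = E @ self.control[:n_free]
        self.Q = E @ self.control[n_free:2 * n_free]
        self.M = E @ self.control[2 * n_free:]
        self.flagged[:] = False


def characteristic_scales(kin) -> tuple[float, float]:
    """Characteristic frequency (Hz) and lateral displacement (m) of a
    kinematics window, used to normalise the equation residuals."""
    eta = kin.eta
    eta_t = kin.eta_t
    denom = float(np.mean(eta**2))
    span = kin.t[-1] - kin.t[0]
    if denom > 0 and np.mean(eta_t**2) > 0:
        f_char = float(np.sqrt(np.mean(eta_t**2) / denom)) / (2 * np.pi)
    else:
        f_char = 0.0
    f_char = max(f_char, 1.0 / max(span, 1e-12))
    eta_char = max(float(np.max(np.abs(eta))), 1e-3 * kin.length)
    return f_char, eta_char


def _operator(kin, body, basis: SplineBasis, j: int, scales=None):
    """Linear residual operator (L, b) at time index j: residual = L u - b,
    u the stacked free control values of N, Q, M, rows normalised."""
    E = basis.eval_op_constrained
    D = basis.deriv_op_constrained
    th = kin.theta[:, j]
    kap = kin.kappa[:, j]
    c, sn = np.cos(th), np.sin(th)
    Z = np.zeros_like(E)
    L1 = np.hstack([c[:, None] * D - (kap * sn)[:, None] * E,
                    -(sn[:, None] * D + (kap * c)[:, None] * E), Z])
    L2 = np.hstack([sn[:, None] * D + (kap * c)[:, None] * E,
                    c[:, None] * D - (kap * sn)[:, None] * E, Z])
    L3 = np.hstack([Z, E, D])
    L = np.vstack([L1, L2, L3])
    return L


def _rhs(kin, loads, body, j):
    b1 = loads.f_x[:, j] - body.mu * kin.xi_tt[:, j]
    b2 = loads.f_y[:, j] - body.mu * kin.eta_tt[:, j]
    b3 = loads.m_z[:, j] - body.rho_fish * body.second_moment * kin.theta_tt[:, j]
    return np.concatenate([b1, b2, b3])


def _row_scales(kin, body, n_s):
    f_char, eta_char = characteristic_scales(kin)
    force_scale = float(np.max(body.mu)) * (2 * np.pi * f_char) ** 2 * eta_char
    moment_scale = force_scale * kin.length
    return np.concatenate([np.full(2 * n_s, force_scale),
                           np.full(n_s, moment_scale)])


def assemble_residuals(trial: dict, kin, loads, body, j: int = 0,
                       basis: SplineBasis | None = None) -> np.ndarray:
    """Normalised residual vector of the beam equations at time index ``j``
    for trial fields given on the collocation grid.

    ``trial`` maps 'N', 'Q', 'M' to arrays on the s grid (a single time
    sample).  Spatial derivatives of the trial fields are evaluated with
    the same grid-resolution quintic-spline machinery used everywhere else.
    """
    from .splines import spline_matrix

    for key in ("N", "Q", "M"):
        if key not in trial:
            raise ValueError(f"trial state is missing field {key!r}")
    for fld in ("xi_tt", "eta_tt", "theta_tt"):
        if getattr(kin, fld, None) is None:
            raise ValueError(f"kinematics are missing derivative field {fld!r}")
    s = kin.s
    Dg = spline_matrix(s, s, 1)
    th = kin.theta[:, j]
    c, sn = np.cos(th), np.sin(th)
    N, Q, M = (np.asarray(trial[k], float) for k in ("N", "Q", "M"))
    r1 = body.mu * kin.xi_tt[:, j] + Dg @ (N * c) - Dg @ (Q * sn) - loads.f_x[:, j]
    r2 = body.mu * kin.eta_tt[:, j] + Dg @ (N * sn) + Dg @ (Q * c) - loads.f_y[:, j]
    r3 = (body.rho_fish * body.second_moment * kin.theta_tt[:, j]
          + Dg @ M + Q - loads.m_z[:, j])
    return np.concatenate([r1, r2, r3]) / _row_scales(kin, body, s.size)


def reconstruct_internal(
    kin,
    loads,
    body,
    n_c: int = 16,
    xtol: float = 1e-10,
    max_iter: int = 200,
) -> InternalState:
    """Reconstruct N, Q, M for all time samples of a kinematics window.

    ``loads`` must be the total external load distribution (fluid +
    fictitious) on the kinematics grids.  Samples are solved independently
    by damped least squares on the end-vanishing constrained spline basis,
    each warm-started from the previous solution; non-converged samples are
    flagged, never silently dropped.
    """
    if not (np.array_equal(loads.s, kin.s) and np.array_equal(loads.t, kin.t)):
        raise ValueError("loads must be sampled on the kinematics grids")
    basis = build_spline_basis(n_c, kin.s)
    n_s = kin.s.size
    n_t = kin.t.size
    n_free = basis.n_free
    scales = _row_scales(kin, body, n_s)

    control = np.zeros((3 * n_free, n_t))
    res_norm = np.zeros(n_t)
    iters = np.zeros(n_t, dtype=int)
    flagged = np.zeros(n_t, dtype=bool)
    u = np.zeros(3 * n_free)  # cold start: zero state

    for j in range(n_t):
        L = _operator(kin, body, basis, j) / scales[:, None]
        b = _rhs(kin, loads, body, j) / scales
        sol = least_squares(
            lambda v: L @ v - b, u, jac=lambda v: L, method="lm",
            xtol=xtol, max_nfev=max_iter,
        )
        u = sol.x
        control[:, j] = u
        res_norm[j] = float(np.sqrt(np.mean(sol.fun**2)))
        iters[j] = sol.nfev
        flagged[j] = sol.status <= 0
    if flagged.all():
        raise RuntimeError("no time sample converged; check inputs")

    E = basis.eval_op_constrained
    return InternalState(
        s=kin.s, t=kin.t,
        N=E @ control[:n_free],
        Q=E @ control[n_free:2 * n_free],
        M=E @ control[2 * n_free:],
        control=control, basis=basis,
        residual_norm=res_norm, iterations=iters, flagged=flagged,
    )


def reconstruction_error(M_rec: np.ndarray, M_ref: np.ndarray
                         ) -> tuple[float, float]:
    """Average and maximum reconstruction error in percent of the reference
    field's global maximum: err(s,t) = |M_rec - M_ref| / max |M_ref|."""
    M_rec = np.asarray(M_rec, float)
    M_ref = np.asarray(M_ref, float)
    if M_rec.shape != M_ref.shape:
        raise ValueError("fields must share a grid")
    peak = np.max(np.abs(M_ref))
    if peak == 0:
        raise ValueError("reference field is identically zero")
    err = np.abs(M_rec - M_ref) / peak * 100.0
    return float(err.mean()), float(err.max())
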