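"""Quintic-spline interpolation machinery shared by all modules.

Fields along the body axis and in time are represented by interpolating
quintic splines through uniformly spaced control points.  Because spline
interpolation is linear in the control values, evaluation and
differentiation are precomputed matrices; this keeps the inverse problem
linear in the unknown control values and makes every derivative used in
the toolkit the analytic derivative of one consistent representation.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import make_interp_spline

__all__ = ["SplineBasis", "spline_matrix", "time_derivatives"]


def spline_matrix(
    x_ctrl: np.ndarray, x_eval: np.ndarray, deriv: int = 0, k: int = 5
) -> np.ndarray:
    """Matrix mapping control values at ``x_ctrl`` to the ``deriv``-th
    derivative of the interpolating spline of degree ``k`` at ``x_eval``.

    Columns are obtained by interpolating the unit vectors, so the map is
    exact for any data and reproduces polynomials up to degree ``k``.
    """
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x_ctrl.size
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} control points, got {n}")
    cols = np.empty((x_eval.size, n))
    eye = np.eye(n)
    for j in range(n):
        spl = make_interp_spline(x_ctrl, eye[j], k=k)
        if deriv:
            spl = spl.derivative(deriv)
        cols[:, j] = spl(x_eval)
    return cols


class SplineBasis:
    """Quintic-spline field on ``[0, L]`` with ``n_c`` uniform control points.

    Provides evaluation and s-derivative operators on a collocation grid,
    both for the unconstrained basis and for the end-vanishing constrained
    variant (every member zero at both ends), used for internal fields that
    must satisfy free-end boundary conditions exactly.
    """

    def __init__(self, n_c: int, s_grid: np.ndarray):
        s_grid = np.asarray(s_grid, dtype=float)
        if n_c < 8:
            raise ValueError(f"n_c must be at least 8, got {n_c}")
        if n_c > s_grid.size:
            raise ValueError(
                f"n_c={n_c} exceeds the collocation grid resolution ({s_grid.size})"
            )
        if s_grid[0] < 0 or np.any(np.diff(s_grid) <= 0):
            raise ValueError("collocation grid must be strictly increasing and >= 0")
        self.n_c = int(n_c)
        self.s_grid = s_grid
        self.length = float(s_grid[-1])
        self.s_ctrl = np.linspace(s_grid[0], s_grid[-1], n_c)
        self.eval_op = spline_matrix(self.s_ctrl, s_grid, 0)
        self.deriv_op = spline_matrix(self.s_ctrl, s_grid, 1)
        # end-vanishing variant: interpolation through zero end values is a
        # spline that vanishes at both ends, so drop the end control points
        self.eval_op_constrained = self.eval_op[:, 1:-1]
        self.deriv_op_constrained = self.deriv_op[:, 1:-1]

    @property
    def n_free(self) -> int:
        """Number of degrees of freedom of the constrained basis."""
        return self.n_c - 2

    def fit(self, values: np.ndarray) -> np.ndarray:
        """Least-squares control values reproducing ``values`` on the grid."""
        return np.linalg.lstsq(self.eval_op, values, rcond=None)[0]


def time_derivatives(t: np.ndarray, field: np.ndarray, orders=(1, 2)):
    """Analytic time derivatives of the quintic spline through ``field``.

    ``field`` has time along its last axis; the time grid may be irregular.
    Returns one array per requested order, each on the same grid.
    """
    t = np.asarray(t, dtype=float)
    field = np.asarray(field, dtype=float)
    if t.size < 7:
        raise ValueError("need at least 7 time samples for quintic differentiation")
    spl = make_interp_spline(t, field, k=5, axis=field.ndim - 1)
    return tuple(spl.derivative(m)(t) for m in orders)


def time_spline(t: np.ndarray, field: np.ndarray):
    """Quintic spline through ``field`` (time on the last axis)."""
    return make_interp_spline(np.asarray(t, float), np.asarray(field, float),
                              k=5, axis=np.asarray(field).ndim - 1)
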