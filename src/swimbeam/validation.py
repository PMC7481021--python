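"""Round-trip validation of the inverse method against forward references.

Forward-integrated reference motion carries the exact internal fields that
occurred; re-reconstructing them from the motion and the applied loads
measures the inverse method's error.  The same references feed the
small-amplitude baseline comparison.
"""

from __future__ import annotations

import numpy as np

from . import config
from .bout_analysis import power_distributions
from .forward_dynamics import ForwardResult, integrate_forward
from .inverse_beam import reconstruct_internal, reconstruction_error
from .kinematics import fictitious_loads
from .small_amplitude import (
    DEFAULT_MODES,
    fit_fourier_motion,
    small_amplitude_moment,
    synthesise,
)

__all__ = [
    "forward_reference",
    "round_trip",
    "small_amplitude_comparison",
    "tail_excursion",
]


def forward_reference(
    level: str = "0.35",
    n_s: int = 101,
    n_d: int = 25,
    steps_per_period: int = 200,
    periods: float = 3.0,
    ramp_periods: float = 1.0,
    save_per_period: int = 50,
) -> tuple[ForwardResult, "object"]:
    """Forward-integrate the reference larva at one actuation level.

    ``level`` is one of '0.12', '0.20', '0.35' (the nominal peak-to-peak
    tail excursion in body lengths) or a float actuation amplitude in N m.
    Returns ``(result, body)`` with the post-transient window only.
    """
    body = config.reference_body(n_s)
    amplitude = config.ACTUATION_LEVELS.get(level, None)
    if amplitude is None:
        amplitude = float(level)
    act = config.reference_actuation(amplitude, ramp_periods)
    fluid = config.reference_fluid(body, ramp_periods)
    passive = config.reference_passive()
    period = 1.0 / act.frequency
    dt = period / steps_per_period
    stride = max(1, steps_per_period // save_per_period)
    result = integrate_forward(
        body, act, passive, fluid,
        dt=dt, duration=(ramp_periods + periods) * period,
        n_d=n_d, save_stride=stride,
        discard_time=(ramp_periods + max(0.0, periods - 2.0)) * period,
    )
    return result, body


def tail_excursion(result: ForwardResult) -> float:
    """Peak-to-peak lateral tail-tip excursion in body lengths."""
    eta_tail = result.kin.eta[-1]
    return float((eta_tail.max() - eta_tail.min()) / result.kin.length)


def round_trip(result: ForwardResult, body, n_c: int = 16):
    """Reconstruct the internal fields from the reference motion and loads.

    Returns ``(state, avg_error_pct, max_error_pct)`` where the errors are
    relative to the maximum of the reference bending moment.
    """
    fict = fictitious_loads(result.kin.frame, result.kin, body)
    total = result.loads + fict
    state = reconstruct_internal(result.kin, total, body, n_c=n_c)
    avg, mx = reconstruction_error(state.M, result.M)
    return state, avg, mx


def small_amplitude_comparison(result: ForwardResult, body,
                               modes=DEFAULT_MODES):
    """Apply the small-amplitude Fourier baseline to a forward reference.

    Fits the odd modes to the lateral (head-frame) displacement and load,
    integrates the linearised moment balance per mode, and returns
    ``(M_small, avg_error_pct, max_error_pct)`` against the recorded truth.
    """
    kin = result.kin
    f = config.TAILBEAT_FREQUENCY
    # the linear balance holds in an inertial frame: use the plane-frame
    # lateral displacement (drift removed) and plane-frame lateral load
    phi = kin.frame.angle
    c, sn = np.cos(phi)[None, :], np.sin(phi)[None, :]
    fy_lab = sn * result.loads.f_x + c * result.loads.f_y
    motion = fit_fourier_motion(kin.y, kin.t, kin.s, f, modes, detrend=True)
    load = fit_fourier_motion(fy_lab, kin.t, kin.s, f, modes)
    M_modes = small_amplitude_moment(motion, load, body)
    M_small = synthesise(M_modes, kin.t)
    avg, mx = reconstruction_error(M_small, result.M)
    return M_small, avg, mx


def resultant_power(result: ForwardResult, body):
    """Power distributions of a forward reference (fluid load as applied)."""
    return power_distributions(result.kin, result.loads, body)
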