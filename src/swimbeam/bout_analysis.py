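"""Aperiodic-bout machinery.

Larval swimming is rarely periodic, so sequences are subdivided into half
tail beats using zero crossings of the mid-body bending moment; each half
beat yields summary statistics (duration, mean speed, mean acceleration,
peak moment), the scalar "swimming effort" E = M_peak / t_half, and the
"swimming vigour" V = m (c v^2 + a) whose coefficient c is fitted by total
least squares against the effort.  Periodic sub-windows (when present) are
found by a shifted-difference periodicity score and phase averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .splines import time_derivatives

__all__ = [
    "HalfBeat",
    "EffortVigourFit",
    "PatternStack",
    "PowerDistribution",
    "periodicity_select",
    "segment_half_beats",
    "phase_average",
    "half_beat_stats",
    "effort",
    "vigour",
    "fit_vigour_coefficient",
    "fit_power_effort_glm",
    "pattern_statistics",
    "power_distributions",
    "wave_speed_per_beat",
    "added_mass_coefficient",
]

MIN_HALF_BEAT_DURATION = 2.5e-3   # s; tail beats above ~200 Hz are noise
MIN_AMPLITUDE_FRACTION = 0.05     # sections below 5 % of the peak are noise
PERIODICITY_THRESHOLD = 35.0      # score threshold for a 3-dpf fish;
                                  # dataset-dependent, exposed as a parameter
PATTERN_GRID = (51, 50)           # body stations x phase bins


# ---------------------------------------------------------------------------
# periodicity and phase averaging

def periodicity_select(kappa: np.ndarray, t: np.ndarray,
                       threshold: float = PERIODICITY_THRESHOLD,
                       n_window_steps: int = 24):
    """Longest sub-window whose periodicity score exceeds ``threshold``.

    For a candidate window the sum of absolute differences (SAD) between
    the curvature field and its time-shifted copy is computed as a function
    of the shift; local minima of this function mark candidate periods.
    The score is the ratio of the window's mean absolute (centred)
    curvature SAD level to the SAD at the deepest local minimum — large
    when the signal repeats almost exactly.  Returns ``((t0, t1), score)``
    or ``(None, best_score)`` when no window qualifies.
    """
    kappa = np.atleast_2d(np.asarray(kappa, float))
    t = np.asarray(t, float)
    n_t = t.size
    dt = np.mean(np.diff(t))

    def window_score(i0, i1):
        k = kappa[:, i0:i1]
        n = i1 - i0
        if n < 16:
            return 0.0
        tau_max = n // 2
        sad = np.empty(tau_max - 1)
        for tau in range(1, tau_max):
            sad[tau - 1] = np.mean(np.abs(k[:, tau:] - k[:, :-tau]))
        level = np.mean(np.abs(k - k.mean()))
        if level == 0:
            return 0.0
        minima, _ = find_peaks(-sad)
        if minima.size == 0:
            return 0.0
        best = sad[minima].min()
        return float(level / max(best, 1e-300 * level) )

    # longest-first search over a coarse grid of window boundaries
    steps = max(1, n_t // n_window_steps)
    best_overall = 0.0
    for length in range(n_t, 15, -steps):
        for i0 in range(0, n_t - length + 1, steps):
            sc = window_score(i0, i0 + length)
            best_overall = max(best_overall, sc)
            if sc > threshold:
                return (t[i0], t[i0 + length - 1]), sc
    return None, best_overall


def phase_average(fields: dict, body_angle: np.ndarray, t: np.ndarray,
                  sign_fields=("kappa", "moment"), n_phase: int = 50):
    """Average fields over half phases bounded by body-angle peaks.

    Half phases alternate in direction; sign-carrying fields are mirrored
    (negated) on alternate half phases before averaging, power-like fields
    are averaged unmirrored.  Returns a dict of (n_s, n_phase) maps.
    """
    body_angle = np.asarray(body_angle, float)
    centred = body_angle - body_angle.mean()
    pk_hi, _ = find_peaks(centred)
    pk_lo, _ = find_peaks(-centred)
    peaks = np.sort(np.concatenate([pk_hi, pk_lo]))
    if peaks.size < 2:
        raise ValueError("fewer than 2 body-angle peaks; cannot phase average")
    out = {}
    phase = np.linspace(0.0, 1.0, n_phase)
    for name, fld in fields.items():
        fld = np.atleast_2d(np.asarray(fld, float))
        stacks = []
        for h, (i0, i1) in enumerate(zip(peaks[:-1], peaks[1:])):
            seg_t = np.linspace(t[i0], t[i1], n_phase)
            k = min(3, i1 - i0)
            seg = make_interp_spline(t[i0:i1 + 1], fld[:, i0:i1 + 1],
                                     k=k, axis=1)(seg_t)
            if name in sign_fields and h % 2 == 1:
                seg = -seg
            stacks.append(seg)
        out[name] = np.mean(stacks, axis=0)
    return out


# ---------------------------------------------------------------------------
# segmentation

def _zero_crossings(signal: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linearly interpolated zero-crossing times of a 1-D signal.

    Samples that are exactly zero count as crossings (a run of zeros counts
    once, at its first sample)."""
    tol = 1e-12 * np.max(np.abs(signal)) if signal.size else 0.0
    sgn = np.where(np.abs(signal) <= tol, 0.0, np.sign(signal))
    exact = [t[i] for i in np.flatnonzero(sgn == 0)
             if i == 0 or sgn[i - 1] != 0]
    idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
    frac = signal[idx] / (signal[idx] - signal[idx + 1])
    times = np.concatenate([t[idx] + frac * (t[idx + 1] - t[idx]), exact])
    return np.unique(times)


def _check_candidate(times, M_mid, t, peak_amp, min_amp, min_dur):
    """Apply the half-beat rules to a retained crossing subset; return the
    per-interval extremum values or None if any rule fails."""
    if len(times) < 4:
        return None
    ext = []
    for t0, t1 in zip(times[:-1], times[1:]):
        if t1 - t0 < min_dur:
            return None
        m = (t >= t0) & (t <= t1)
        if not m.any():
            return None
        seg = M_mid[m]
        j = np.argmax(np.abs(seg))
        if np.abs(seg[j]) < min_amp * peak_amp:
            return None
        ext.append(seg[j])
    ext = np.asarray(ext)
    if np.any(np.sign(ext[1:]) * np.sign(ext[:-1]) >= 0):
        return None  # extrema must alternate direction
    return ext


def segment_half_beats(M_mid: np.ndarray, t: np.ndarray,
                       min_amplitude_fraction: float = MIN_AMPLITUDE_FRACTION,
                       min_duration: float = MIN_HALF_BEAT_DURATION,
                       max_enumerate: int = 14,
                       duration_quantum: float = 2.5e-4):
    """Segment a mid-body moment trace into half tail beats.

    Zero crossings of ``M_mid`` delimit candidate half beats.  Crossings
    adjacent to a section whose amplitude is below 5 % of the sequence peak
    are probably noise; every subset of these droppable crossings is
    enumerated (firm crossings are always retained).  A candidate survives
    when every retained section has amplitude >= 5 % of the peak, more than
    three crossings remain, extremum signs alternate, and every duration is
    >= 2.5 ms.  Among survivors the one minimising the standard deviation
    of half-period lengths wins (the spread is quantised to
    ``duration_quantum`` so float jitter cannot decide; ties go to the
    candidate with more half beats, then the earliest start).  Returns a
    list of (t_start, t_end, polarity) tuples (possibly empty) and a dict
    of diagnostic counts.
    """
    M_mid = np.asarray(M_mid, float)
    t = np.asarray(t, float)
    crossings = _zero_crossings(M_mid, t)
    reasons = {"too_few_crossings": 0, "amplitude": 0, "duration": 0,
               "alternation": 0, "survivors": 0}
    if crossings.size < 4:
        reasons["too_few_crossings"] += 1
        return [], reasons
    peak_amp = float(np.max(np.abs(M_mid)))

    def section_amp(t0, t1):
        m = (t >= t0) & (t <= t1)
        return float(np.max(np.abs(M_mid[m]))) if m.any() else 0.0

    amps = np.array([section_amp(a, b)
                     for a, b in zip(crossings[:-1], crossings[1:])])
    weak = amps < min_amplitude_fraction * peak_amp
    droppable = np.zeros(crossings.size, dtype=bool)
    droppable[:-1] |= weak
    droppable[1:] |= weak
    drop_idx = np.flatnonzero(droppable)
    if drop_idx.size > max_enumerate:
        # keep only the most ambiguous ones for enumeration; crossings
        # bounded by two weak sections are dropped outright
        both_weak = np.zeros(crossings.size, dtype=bool)
        both_weak[1:-1] = weak[1:] & weak[:-1]
        keep = ~both_weak
        crossings = crossings[keep]
        droppable = droppable[keep]
        drop_idx = np.flatnonzero(droppable)[:max_enumerate]

    best = None
    n_drop = drop_idx.size
    for mask in itertools.product((True, False), repeat=n_drop):
        keep = np.ones(crossings.size, dtype=bool)
        keep[drop_idx[np.array(mask, bool)]] = False
        times = crossings[keep]
        ext = _check_candidate(times, M_mid, t, peak_amp,
                               min_amplitude_fraction, min_duration)
        if ext is None:
            continue
        reasons["survivors"] += 1
        durations = np.diff(times)
        spread = np.round(np.std(durations) / duration_quantum)
        key = (spread, -len(durations), times[0])
        if best is None or key < best[0]:
            best = (key, times, ext)
    if best is None:
        times = crossings
        if len(times) < 4:
            reasons["too_few_crossings"] += 1
        elif np.any(np.diff(times) < min_duration):
            reasons["duration"] += 1
        else:
            reasons["amplitude"] += 1
        return [], reasons
    _, times, ext = best
    return [(t0, t1, float(np.sign(e)))
            for t0, t1, e in zip(times[:-1], times[1:], ext)], reasons


# ---------------------------------------------------------------------------
# per-half-beat statistics

@dataclass
class HalfBeat:
    """One segmented half tail beat and its summary statistics."""

    t_start: float
    t_end: float
    duration: float
    mean_speed: float                   # m/s, centre-of-mass speed
    mean_acceleration: float | None     # m/s^2; None for the last half beat
    M_peak: float                       # N m, 95th percentile of |M|
    effort: float                       # N m / s
    polarity: float = 1.0
    mirrored: bool = False
    pattern: np.ndarray | None = None   # peak-normalised M on the fixed grid

    def __post_init__(self):
        if self.duration < MIN_HALF_BEAT_DURATION - 1e-12:
            raise ValueError("half beat shorter than the 2.5 ms minimum")


def effort(M_peak: float, t_half: float) -> float:
    """Swimming effort E = M_peak / t_half."""
    if t_half <= 0:
        raise ValueError("half-beat duration must be positive")
    return M_peak / t_half


def vigour(m: float, v: float, a: float, c: float) -> float:
    """Swimming vigour V = m (c v^2 + a)."""
    if m <= 0:
        raise ValueError("body mass must be positive")
    return m * (c * v**2 + a)


def half_beat_stats(boundaries, M: np.ndarray, t: np.ndarray, s: np.ndarray,
                    com: np.ndarray, body, percentile: float = 95.0,
                    pattern_grid=PATTERN_GRID) -> list[HalfBeat]:
    """Half-beat records from segmentation boundaries.

    ``com`` is the (2, n_t) centre-of-mass trajectory.  Mean speed averages
    the centre-of-mass speed over the half beat; mean acceleration is the
    speed difference to the next half beat divided by the midpoint time
    difference (absent for the last half beat).  M_peak is the 95th
    percentile (linear interpolation between order statistics) of |M| over
    all (s, t) samples within the half beat.  Patterns are |M|-peak
    normalised on the fixed normalised grid, negative-polarity beats
    mirrored toward the same side.
    """
    import warnings

    (speed_x,) = time_derivatives(t, com[0], orders=(1,))
    (speed_y,) = time_derivatives(t, com[1], orders=(1,))
    speed = np.hypot(speed_x, speed_y)
    n_sta, n_phase = pattern_grid
    u_grid = np.linspace(0, 1, n_sta)
    records = []
    mids, vbars = [], []
    for t0, t1, pol in boundaries:
        m = (t >= t0) & (t <= t1)
        vbars.append(float(np.mean(speed[m])))
        mids.append(0.5 * (t0 + t1))
    if len(boundaries) == 1:
        warnings.warn("single half beat: no mean acceleration can be computed")
    for i, (t0, t1, pol) in enumerate(boundaries):
        m = (t >= t0) & (t <= t1)
        Mseg = M[:, m]
        M_peak = float(np.percentile(np.abs(Mseg), percentile))
        dur = t1 - t0
        accel = None
        if i + 1 < len(boundaries):
            accel = (vbars[i + 1] - vbars[i]) / (mids[i + 1] - mids[i])
        # resample onto the fixed normalised grid (spline in both axes)
        tseg = np.linspace(t0, t1, n_phase)
        tm = t[m]
        kt = min(5, tm.size - 1)
        patt = make_interp_spline(tm, Mseg, k=max(1, kt), axis=1)(tseg)
        ks = min(5, s.size - 1)
        patt = make_interp_spline(s / s[-1], patt, k=ks, axis=0)(u_grid)
        mirrored = pol < 0
        if mirrored:
            patt = -patt
        peak_abs = np.max(np.abs(patt))
        if peak_abs > 0:
            patt = patt / peak_abs
        records.append(HalfBeat(
            t_start=t0, t_end=t1, duration=dur, mean_speed=vbars[i],
            mean_acceleration=accel, M_peak=M_peak,
            effort=effort(M_peak, dur), polarity=pol, mirrored=mirrored,
            pattern=patt,
        ))
    return records


def half_beat_table(records: list[HalfBeat], mass: float,
                    c: float | None = None, sequence_id=0) -> pd.DataFrame:
    rows = []
    for i, hb in enumerate(records):
        row = {
            "sequence_id": sequence_id, "halfbeat_id": i,
            "t_start_s": hb.t_start, "t_half_s": hb.duration,
            "v_mps": hb.mean_speed, "a_mps2": hb.mean_acceleration,
            "Mpeak_Nm": hb.M_peak, "E_Nmps": hb.effort, "m_kg": mass,
        }
        if c is not None and hb.mean_acceleration is not None:
            row["V_N"] = vigour(mass, hb.mean_speed, hb.mean_acceleration, c)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effort-vigour statistics

@dataclass
class EffortVigourFit:
    c: float                   # vigour coefficient (1/m)
    objective: float           # TLS objective at the optimum
    glm_exponent: float | None = None
    glm_exponent_se: float | None = None
    glm_family: str = "Gamma(log link)"


def _tls_objective(E, V):
    """Sum of squared orthogonal distances of standardised (E, V) points to
    their best-fitting line (with intercept)."""
    x = (E - E.mean())
    y = (V - V.mean())
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.inf
    pts = np.column_stack([x / sx, y / sy])
    # orthogonal residuals: variance along the minor principal axis
    _, sv, _ = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
    return float(sv[-1] ** 2)


def fit_vigour_coefficient(table: pd.DataFrame,
                           c_bounds=(1.0, 1e4)) -> EffortVigourFit:
    """Fit the vigour coefficient c by nested optimisation.

    Outer: scalar search over c.  Inner: total-least-squares line fit of
    V(c) = m (c v^2 + a) against E on standardised variables; the objective
    is the sum of squared orthogonal distances.
    """
    req = {"m_kg", "v_mps", "a_mps2", "E_Nmps"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must carry columns {sorted(req)}")
    df = table.dropna(subset=["a_mps2"])
    if len(df) < 10:
        raise ValueError("need at least 10 half beats with speed and acceleration")
    m = df["m_kg"].to_numpy()
    v2 = df["v_mps"].to_numpy() ** 2
    a = df["a_mps2"].to_numpy()
    E = df["E_Nmps"].to_numpy()
    if np.std(v2) < 1e-300 or np.std(a) < 1e-300:
        raise ValueError("degenerate data: no contrast in v^2 or a")
    r = np.corrcoef(v2, a)[0, 1]
    if abs(r) > 0.999:
        raise ValueError("degenerate data: v^2 and a are collinear")

    def obj(log_c):
        c = 10.0 ** log_c
        return _tls_objective(E, m * (c * v2 + a))

    res = minimize_scalar(obj, bounds=np.log10(c_bounds), method="bounded",
                          options={"xatol": 1e-10})
    c_hat = float(10.0 ** res.x)
    fit = EffortVigourFit(c=c_hat, objective=float(res.fun))
    V = m * (c_hat * v2 + a)
    pos = (V > 0) & (E > 0)
    if pos.sum() >= 10:
        exp_, se_ = _gamma_loglink(E[pos], V[pos])
        fit.glm_exponent, fit.glm_exponent_se = exp_, se_
    return fit


def _gamma_loglink(E, y):
    import statsmodels.api as sm

    X = sm.add_constant(np.log(E))
    model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
    try:
        resfit = model.fit()
        return float(resfit.params[1]), float(resfit.bse[1])
    except ValueError:
        # degenerate (e.g. exactly constant) response: the gamma deviance
        # collapses; the log-log least-squares slope is the same exponent
        # estimate and is well defined here
        ols = sm.OLS(np.log(y), X).fit()
        return float(ols.params[1]), float(ols.bse[1])


def fit_power_effort_glm(E: np.ndarray, P: np.ndarray):
    """Gamma GLM (log link) of mean resultant power on log effort.

    Returns ``(exponent, standard_error)``; an exponent near 1 means power
    grows linearly with effort.  Non-positive powers are dropped (gamma
    support) and logged.
    """
    import logging

    E = np.asarray(E, float)
    P = np.asarray(P, float)
    good = (P > 0) & (E > 0) & np.isfinite(P) & np.isfinite(E)
    if (~good).sum():
        logging.getLogger(__name__).info(
            "fit_power_effort_glm: dropping %d non-positive records",
            int((~good).sum()))
    if good.sum() < 3:
        raise ValueError("too few positive records for the gamma GLM")
    return _gamma_loglink(E[good], P[good])


# ---------------------------------------------------------------------------
# pattern statistics

@dataclass
class PatternStack:
    patterns: np.ndarray       # (n_beats, n_sta, n_phase)
    mean: np.ndarray
    sd: np.ndarray
    mad: np.ndarray            # per-beat mean |pattern - mean|
    centre_of_volume: np.ndarray  # (n_beats, 2): body fraction, phase fraction


def pattern_statistics(patterns) -> PatternStack:
    """Mean pattern, pointwise SD, per-beat MAD and centre of volume.

    Patterns must already be peak-normalised on a common grid (mirrored
    toward the same side).  The centre of volume weights each grid point by
    max(M, 0) — after mirroring the patterns are predominantly positive and
    residual negative lobes are clipped.
    """
    arr = np.asarray([np.asarray(p, float) for p in patterns])
    if arr.size == 0:
        raise ValueError("empty pattern stack")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    mad = np.array([np.mean(np.abs(p - mean)) for p in arr])
    n_sta, n_phase = arr.shape[1:]
    u = np.linspace(0, 1, n_sta)[:, None]
    ph = np.linspace(0, 1, n_phase)[None, :]
    cov = []
    for p in arr:
        w = np.clip(p, 0.0, None)
        tot = w.sum()
        if tot == 0:
            cov.append((0.5, 0.5))
        else:
            cov.append(((w * u).sum() / tot, (w * ph).sum() / tot))
    return PatternStack(patterns=arr, mean=mean, sd=sd, mad=mad,
                        centre_of_volume=np.asarray(cov))


# ---------------------------------------------------------------------------
# power distributions

@dataclass
class PowerDistribution:
    s: np.ndarray
    t: np.ndarray
    fluid: np.ndarray      # W/m, power exerted by the body on the fluid
    kinetic: np.ndarray    # W/m, rate of change of local kinetic energy
    resultant: np.ndarray  # fluid + kinetic

    def mean_resultant(self, t0: float, t1: float) -> float:
        """Body-integrated resultant power averaged over [t0, t1]."""
        m = (self.t >= t0) & (self.t <= t1)
        tot = np.trapezoid(self.resultant[:, m], self.s, axis=0)
        return float(np.mean(tot))


def power_distributions(kin, fluid_loads, body) -> PowerDistribution:
    """Fluid, kinetic, and resultant power per unit length.

    P_fluid = -(f_fluid . v_lab): positive when the body does work on the
    water.  P_kin = d/dt [ mu |v|^2 / 2 + rho I omega^2 / 2 ].  The fluid
    load is given in head-frame components and is rotated back to the plane
    frame before the dot product.
    """
    vx, vy = kin.lab_velocity()
    if vx is None:
        raise ValueError("kinematics lack velocity fields")
    phi = kin.frame.angle
    c, sn = np.cos(phi)[None, :], np.sin(phi)[None, :]
    fx_lab = c * fluid_loads.f_x - sn * fluid_loads.f_y
    fy_lab = sn * fluid_loads.f_x + c * fluid_loads.f_y
    p_fluid = -(fx_lab * vx + fy_lab * vy)
    omega_lab = kin.theta_t + kin.frame.omega[None, :]
    ke_density = (0.5 * body.mu[:, None] * (vx**2 + vy**2)
                  + 0.5 * body.rho_fish * body.second_moment[:, None]
                  * omega_lab**2)
    (p_kin,) = time_derivatives(kin.t, ke_density, orders=(1,))
    return PowerDistribution(s=kin.s, t=kin.t, fluid=p_fluid, kinetic=p_kin,
                             resultant=p_fluid + p_kin)


def wave_speed_per_beat(field: np.ndarray, s: np.ndarray, t: np.ndarray,
                        frequency: float, s_range=(0.3, 0.8)) -> float:
    """Posterior travelling-wave speed of a field in body lengths per beat.

    The phase of the fundamental component is fitted linearly over the
    mid-body; the wave advances one wavelength per period, so the speed in
    body lengths per tail beat equals wavelength / body length.
    """
    field = np.asarray(field, float)
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    z = np.trapezoid(field * np.exp(-2j * np.pi * frequency * t)[None, :],
                     t, axis=1)
    u = s / s[-1]
    m = (u >= s_range[0]) & (u <= s_range[1]) & (np.abs(z) > 0.05 * np.abs(z).max())
    if m.sum() < 3:
        raise ValueError("too little wave content to estimate a speed")
    phase = np.unwrap(np.angle(z[m]))
    slope = np.polyfit(s[m], phase, 1)[0]
    if slope == 0:
        return np.inf
    wavelength = 2 * np.pi / abs(slope)
    return float(wavelength / s[-1])


def added_mass_coefficient(c: float, c_d: float, rho_w: float, S: float,
                           m: float) -> float:
    """Added-mass coefficient from the vigour coefficient.

    Balancing the velocity contribution c_d (1/2) rho_w S v^2 against the
    acceleration contribution m (1 + c_m) a in V = m (c v^2 + a) gives
    c_m = c_d rho_w S / (2 m c) - 1.
    """
    if min(c, c_d, rho_w, S, m) <= 0:
        raise ValueError("all inputs must be positive")
    return c_d * rho_w * S / (2.0 * m * c) - 1.0
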