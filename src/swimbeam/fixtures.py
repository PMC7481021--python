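"""Deterministic fixture generation.

Three kinds of fixture emulate the study conditions: a travelling-wave
swimmer (larval zebrafish kinematics: millimetre-scale body, tens-of-Hz
tail beat, curvature waves launched behind the stiff head), a
forward-integrated reference with ground-truth internal fields, and a toy
aperiodic bout for the segmentation/effort statistics.  Everything is
deterministic given (kind, seed, parameters).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import config, io
from .kinematics import compute_deformation_state, make_travelling_wave
from .loads import resistive_load
from .morphology import write_body_table
from .validation import forward_reference

__all__ = [
    "make_fixture",
    "make_effort_vigour_table",
    "make_power_effort_samples",
    "toy_bout",
]


def make_effort_vigour_table(n: int = 285, c_true: float = 500.0,
                             noise: float = 0.0, seed: int = 0,
                             mass: float = 3.0e-7) -> pd.DataFrame:
    """Synthetic half-beat table on which vigour is exactly (or noisily)
    proportional to effort under the true coefficient ``c_true``.

    Speeds, durations and efforts span the ranges observed for larval
    zebrafish (speeds up to ~0.1 m/s, half beats 3-20 ms).  Accelerations
    are back-computed so that V = m (c_true v^2 + a) = k E; multiplicative
    lognormal noise of relative magnitude ``noise`` perturbs V via a.
    """
    rng = np.random.default_rng(seed)
    t_half = 10 ** rng.uniform(np.log10(3e-3), np.log10(20e-3), n)
    v = rng.uniform(0.005, 0.1, n)
    E = 10 ** rng.uniform(-7.5, -5.5, n)
    k = 0.5  # N per (N m / s): vigour-per-effort slope
    V = k * E
    if noise > 0:
        V = V * np.exp(rng.normal(0.0, noise, n))
    a = V / mass - c_true * v**2
    return pd.DataFrame({
        "sequence_id": 0, "halfbeat_id": np.arange(n),
        "t_half_s": t_half, "v_mps": v, "a_mps2": a,
        "Mpeak_Nm": E * t_half, "E_Nmps": E, "m_kg": mass,
    })


def make_power_effort_samples(n: int = 400, exponent: float = 1.3,
                              scale: float = 2.0, shape: float = 20.0,
                              seed: int = 0):
    """Synthetic (E, P) pairs with P = scale * E**exponent times
    multiplicative gamma noise of the given shape."""
    rng = np.random.default_rng(seed)
    E = 10 ** rng.uniform(-7.5, -5.5, n)
    P = scale * E**exponent * rng.gamma(shape, 1.0 / shape, n)
    return E, P


def toy_bout(seed: int = 0, n_halfbeats: int = 8, n_s: int = 31,
             base_frequency: float = 60.0, mass: float = 3.0e-7):
    """Aperiodic toy bout: a mid-body moment trace of ``n_halfbeats``
    alternating lobes with jittered durations and amplitudes, a matching
    moment field, and a centre-of-mass trajectory with varying speed.

    Returns ``(M, M_mid, com, t, s)``.
    """
    rng = np.random.default_rng(seed)
    L = config.BODY_LENGTH
    s = np.linspace(0.0, L, n_s)
    durations = (0.5 / base_frequency) * rng.uniform(0.85, 1.3, n_halfbeats)
    amps = 4e-9 * rng.uniform(0.5, 1.2, n_halfbeats)
    dt = 1.0 / 4000.0
    t_edges = np.concatenate([[0.0], np.cumsum(durations)])
    t = np.arange(0.0, t_edges[-1], dt)
    M_mid = np.zeros_like(t)
    for i, (t0, t1) in enumerate(zip(t_edges[:-1], t_edges[1:])):
        m = (t >= t0) & (t < t1)
        M_mid[m] = ((-1) ** i) * amps[i] * np.sin(
            np.pi * (t[m] - t0) / (t1 - t0))
    u = s / L
    env = np.sin(np.pi * u) ** 2
    M = env[:, None] * M_mid[None, :]
    speed = 0.02 + 0.015 * np.sin(2 * np.pi * t / t_edges[-1]) \
        + 0.002 * rng.standard_normal()
    com = np.stack([np.cumsum(speed) * dt, np.zeros_like(t)])
    return M, M_mid, com, t, s


def make_fixture(kind: str, seed: int, out_dir, **params) -> dict:
    """Write fixture files and return the mapping of artefact names to paths.

    Kinds: ``travelling_wave`` (kinematics + resistive loads + body),
    ``forward_reference`` (adds the ground-truth internal fields), and
    ``toy_bout`` (mid-body moment field + centre-of-mass track).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if kind == "travelling_wave":
        n_s = params.get("n_s", 61)
        body = config.reference_body(n_s)
        amp = params.get("curvature_amplitude", 300.0)  # 1/m at the tail
        freq = params.get("frequency", config.TAILBEAT_FREQUENCY)
        env = amp * (body.s / body.length) ** 2
        kin = make_travelling_wave(env, freq, config.ACTUATION_WAVELENGTH,
                                   params.get("duration", 2.0 / freq), body,
                                   n_t=params.get("n_t", 101))
        loads = resistive_load(kin, body)
        paths["body"] = out / "body.csv"
        write_body_table(body, paths["body"])
        paths["kinematics"] = out / "kinematics.csv"
        io.write_kinematics_table(paths["kinematics"], kin.x, kin.y, kin.t,
                                  kin.s)
        paths["loads"] = out / "loads.csv"
        io.write_loads_table(paths["loads"], loads)
    elif kind == "forward_reference":
        level = params.get("level", "0.35")
        result, body = forward_reference(
            level,
            n_s=params.get("n_s", 61),
            n_d=params.get("n_d", 21),
            steps_per_period=params.get("steps_per_period", 200),
            periods=params.get("periods", 2.0),
        )
        paths["body"] = out / "body.csv"
        write_body_table(body, paths["body"])
        paths["kinematics"] = out / "kinematics.csv"
        io.write_kinematics_table(paths["kinematics"], result.kin.x,
                                  result.kin.y, result.kin.t, result.kin.s)
        paths["loads"] = out / "loads.csv"
        io.write_loads_table(paths["loads"], result.loads)
        paths["truth"] = out / "reference.h5"
        io.write_field_container(paths["truth"], result.kin, extras={
            "N_truth": result.N, "Q_truth": result.Q, "M_truth": result.M,
            "M_active": result.M_active,
        })
    elif kind == "toy_bout":
        M, M_mid, com, t, s = toy_bout(seed=seed, **params)
        paths["bout"] = out / "toy_bout.h5"
        import h5py

        with h5py.File(paths["bout"], "w") as f:
            for name, data in (("t", t), ("s", s), ("M", M),
                               ("M_mid", M_mid), ("com", com)):
                f.create_dataset(name, data=data)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return {k: str(v) for k, v in paths.items()}
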