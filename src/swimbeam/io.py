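"""File formats: delimited tables, the HDF5 field container, run configs.

All on-disk quantities are SI.  Text tables are UTF-8, comma-separated
with a mandatory header row and period decimal separator; floats are
written with 17 significant digits so a text round trip reproduces values
to better than 1e-12 relative.  Gridded fields travel in an HDF5 container
(bit-exact round trip).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .kinematics import CentrelineKinematics, compute_deformation_state
from .loads import LoadDistribution

FLOAT_FMT = "%.17g"

KINEMATICS_COLUMNS = ("t_s", "s_m", "x_m", "y_m")
LOADS_COLUMNS = ("t_s", "s_m", "fx_Npm", "fy_Npm", "mz_N")


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s) {missing}")


def _long_to_grid(df: pd.DataFrame, value_cols):
    t = np.unique(df["t_s"].to_numpy())
    s = np.unique(df["s_m"].to_numpy())
    if len(df) != t.size * s.size:
        raise ValueError(
            f"table is not a full rectangular grid: {len(df)} rows for "
            f"{s.size} stations x {t.size} times")
    out = []
    piv = df.sort_values(["t_s", "s_m"])
    for col in value_cols:
        arr = piv[col].to_numpy().reshape(t.size, s.size).T
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"NaN in column {col!r} at s index {i}, t index {j}")
        out.append(arr)
    return t, s, out


def write_kinematics_table(path, x, y, t, s, z=None) -> None:
    tt, ss = np.meshgrid(t, s, indexing="ij")
    data = {"t_s": tt.ravel(), "s_m": ss.ravel(),
            "x_m": np.asarray(x).T.ravel(), "y_m": np.asarray(y).T.ravel()}
    if z is not None:
        data["z_m"] = np.asarray(z).T.ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_kinematics_table(path):
    """Read a long-format kinematics table; returns ``(x, y, t, s)`` or,
    when a z_m column is present, ``(x, y, z, t, s)`` (to be plane-projected)."""
    df = pd.read_csv(path)
    _require_columns(df, KINEMATICS_COLUMNS, "kinematics table")
    cols = ["x_m", "y_m"] + (["z_m"] if "z_m" in df.columns else [])
    t, s, arrs = _long_to_grid(df, cols)
    if "z_m" in df.columns:
        return arrs[0], arrs[1], arrs[2], t, s
    return arrs[0], arrs[1], t, s


def write_loads_table(path, loads: LoadDistribution) -> None:
    tt, ss = np.meshgrid(loads.t, loads.s, indexing="ij")
    pd.DataFrame({
        "t_s": tt.ravel(), "s_m": ss.ravel(),
        "fx_Npm": loads.f_x.T.ravel(), "fy_Npm": loads.f_y.T.ravel(),
        "mz_N": loads.m_z.T.ravel(),
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_loads_table(path, provenance: str = "fluid") -> LoadDistribution:
    df = pd.read_csv(path)
    _require_columns(df, LOADS_COLUMNS, "loads table")
    t, s, (fx, fy, mz) = _long_to_grid(df, ["fx_Npm", "fy_Npm", "mz_N"])
    return LoadDistribution(s=s, t=t, f_x=fx, f_y=fy, m_z=mz,
                            provenance=provenance)


def write_field_container(path, kin: CentrelineKinematics, state=None,
                          extras: dict | None = None) -> None:
    """HDF5 container with the kinematic fields, their derivatives, and
    optionally a reconstructed internal state."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=kin.t)
        f.create_dataset("s", data=kin.s)
        for name in ("x", "y", "xi", "eta", "theta", "kappa", "stretch",
                     "body_angle"):
            f.create_dataset(name, data=getattr(kin, name))
        g = f.create_group("derivatives")
        for name in ("xi_t", "xi_tt", "eta_t", "eta_tt", "theta_t",
                     "theta_tt", "kappa_t"):
            g.create_dataset(name, data=getattr(kin, name))
        fr = f.create_group("frame")
        for name in ("origin", "angle", "a0", "omega", "omega_dot"):
            fr.create_dataset(name, data=getattr(kin.frame, name))
        if state is not None:
            st = f.create_group("internal")
            for name in ("N", "Q", "M", "residual_norm", "flagged"):
                st.create_dataset(name, data=getattr(state, name))
        for key, val in (extras or {}).items():
            f.create_dataset(f"extras/{key}", data=val)


def read_field_container(path):
    """Read the container back; returns ``(kin, internal_dict_or_None)``."""
    with h5py.File(path, "r") as f:
        t = f["t"][()]
        s = f["s"][()]
        x = f["x"][()]
        y = f["y"][()]
        kin = compute_deformation_state(x, y, t, s)
        internal = None
        if "internal" in f:
            internal = {k: f["internal"][k][()] for k in f["internal"]}
    return kin, internal


def write_halfbeat_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_halfbeat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("t_half_s", "Mpeak_Nm", "E_Nmps"), "half-beat table")
    return df


_S1_COLUMN_MAP = {
    "speed": "v_mps", "velocity": "v_mps", "v": "v_mps",
    "acceleration": "a_mps2", "a": "a_mps2",
    "effort": "E_Nmps", "e": "E_Nmps",
    "vigour": "V_N", "vigor": "V_N",
    "power": "P_W", "p": "P_W",
    "duration": "t_half_s", "t_half": "t_half_s",
    "moment": "Mpeak_Nm", "m_peak": "Mpeak_Nm", "mpeak": "Mpeak_Nm",
    "mass": "m_kg", "m": "m_kg", "length": "length_m",
}


def read_s1_data(path, sheet=None) -> pd.DataFrame:
    """Read a per-half-beat sheet from the supplementary spreadsheet layout
    (sheet-per-figure XLSX) and map its columns onto the half-beat table
    schema.  Column matching is case-insensitive on the leading word."""
    sheets = pd.read_excel(path, sheet_name=sheet)
    if isinstance(sheets, dict):
        frames = list(sheets.values())
    else:
        frames = [sheets]
    best, best_hits = None, 0
    for df in frames:
        renamed = {}
        for col in df.columns:
            key = str(col).strip().lower().split()[0].split("_")[0].rstrip("(")
            if key in _S1_COLUMN_MAP:
                renamed[col] = _S1_COLUMN_MAP[key]
        if len(renamed) > best_hits:
            best, best_hits = df.rename(columns=renamed), len(renamed)
    if best is None or best_hits < 2:
        raise ValueError("no sheet with recognisable half-beat columns found")
    return best


@dataclass
class RunConfig:
    """Fully resolved run configuration; unknown keys are rejected."""

    body: str | None = None
    kinematics: str | None = None
    loads: str | None = None
    out_dir: str = "."
    seed: int = 0
    verbosity: str = "INFO"
    n_control: int = 16
    periodicity_threshold: float = 35.0
    min_half_beat_duration: float = 2.5e-3
    min_amplitude_fraction: float = 0.05
    simulation: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
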