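"""Geometric and inertial distributions of the swimmer's body.

The fish is reduced to a slender beam along its central axis.  Each
transversal slice is an ellipse with lateral axis ``w`` (width) and
dorsoventral axis ``h`` (height); this closure keeps the section area and
second moment of area analytic:

    A(s) = (pi/4) w h            (cross-sectional area)
    I(s) = (pi/64) h w**3        (second moment for lateral bending,
                                  about the dorsoventral centroidal axis)

Mass per unit length is mu(s) = rho_fish * A(s); total mass and wetted
area follow by quadrature along the axis.  Tissue density defaults to
1000 kg/m^3 (neutral buoyancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.interpolate import make_interp_spline

__all__ = ["BodyModel", "build_body_model", "read_body_table", "write_body_table"]

RHO_FISH_DEFAULT = 1000.0  # kg/m^3, neutral buoyancy


@dataclass
class BodyModel:
    """Geometry and inertia of the swimmer along its central axis (SI units)."""

    s: np.ndarray            # arc grid, 0 at snout .. length at tail tip (m)
    width: np.ndarray        # lateral extent w(s) (m)
    height: np.ndarray       # dorsoventral extent h(s) (m)
    rho_fish: float          # tissue density (kg/m^3)
    muscle_area: np.ndarray | None = None  # optional a_m(s) (m^2)
    area: np.ndarray = field(init=False)
    second_moment: np.ndarray = field(init=False)
    mu: np.ndarray = field(init=False)     # mass per unit length (kg/m)
    mass: float = field(init=False)        # total mass (kg)
    wetted_area: float = field(init=False)  # S (m^2)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.s.ndim != 1 or self.s.size < 2:
            raise ValueError("arc grid must be 1-D with at least two stations")
        if self.s[0] != 0.0 or np.any(np.diff(self.s) <= 0):
            raise ValueError("arc grid must be strictly increasing with s[0] = 0")
        if self.length <= 0:
            raise ValueError("body length must be positive")
        for name, prof in (("width", self.width), ("height", self.height)):
            bad = np.flatnonzero(prof < 0)
            if bad.size:
                raise ValueError(
                    f"negative {name} profile value at station index {bad[0]} "
                    f"(s = {self.s[bad[0]]:.6g} m)"
                )
        self.area = 0.25 * np.pi * self.width * self.height
        self.second_moment = (np.pi / 64.0) * self.height * self.width**3
        self.mu = self.rho_fish * self.area
        self.mass = float(simpson(self.mu, x=self.s))
        # ellipse perimeter (Ramanujan's approximation) integrated along s
        a, b = self.width / 2.0, self.height / 2.0
        hpar = np.zeros_like(a)
        nz = (a + b) > 0
        hpar[nz] = ((a[nz] - b[nz]) / (a[nz] + b[nz])) ** 2
        per = np.pi * (a + b) * (1 + 3 * hpar / (10 + np.sqrt(4 - 3 * hpar)))
        self.wetted_area = float(simpson(per, x=self.s))

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def interpolated(self, s_new: np.ndarray) -> "BodyModel":
        """Body model resampled (cubic, clipped at zero) onto a new arc grid."""
        s_new = np.asarray(s_new, dtype=float)
        w = np.clip(make_interp_spline(self.s, self.width, k=3)(s_new), 0.0, None)
        h = np.clip(make_interp_spline(self.s, self.height, k=3)(s_new), 0.0, None)
        am = None
        if self.muscle_area is not None:
            am = np.clip(make_interp_spline(self.s, self.muscle_area, k=3)(s_new), 0.0, None)
        return BodyModel(s=s_new, width=w, height=h, rho_fish=self.rho_fish,
                         muscle_area=am)


def build_body_model(
    s_profile: np.ndarray,
    width_profile: np.ndarray,
    height_profile: np.ndarray,
    rho_fish: float = RHO_FISH_DEFAULT,
    n_s: int = 101,
    muscle_area: np.ndarray | None = None,
) -> BodyModel:
    """Build a :class:`BodyModel` on ``n_s`` uniform stations from sampled
    width/height profiles defined on ``[0, L]``.
    """
    s_profile = np.asarray(s_profile, dtype=float)
    if n_s < 11:
        raise ValueError("n_s must be at least 11")
    if s_profile[-1] <= 0:
        raise ValueError("body length must be positive")
    model = BodyModel(
        s=s_profile,
        width=np.asarray(width_profile, dtype=float),
        height=np.asarray(height_profile, dtype=float),
        rho_fish=rho_fish,
        muscle_area=None if muscle_area is None else np.asarray(muscle_area, float),
    )
    return model.interpolated(np.linspace(0.0, s_profile[-1], n_s))


def read_body_table(path) -> BodyModel:
    """Read a morphology table (columns s_m, width_m, height_m[, muscle_area_m2])."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("s_m", "width_m", "height_m"):
        if col not in df.columns:
            raise ValueError(f"morphology table is missing required column {col!r}")
    am = df["muscle_area_m2"].to_numpy() if "muscle_area_m2" in df.columns else None
    return BodyModel(
        s=df["s_m"].to_numpy(),
        width=df["width_m"].to_numpy(),
        height=df["height_m"].to_numpy(),
        rho_fish=RHO_FISH_DEFAULT,
        muscle_area=am,
    )


def write_body_table(model: BodyModel, path) -> None:
    df = pd.DataFrame({"s_m": model.s, "width_m": model.width,
                       "height_m": model.height})
    if model.muscle_area is not None:
        df["muscle_area_m2"] = model.muscle_area
    df.to_csv(path, index=False, float_format="%.12e")
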