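"""Per-unit-length external load distributions.

Loads enter the beam equations as forces per unit length ``f_x``, ``f_y``
(head-frame components, N/m) and a distributed moment ``m_z`` (N), sampled
on the kinematics (s, t) grids.  They can be prescribed analytically
(cosine forcing), produced by a quadratic resistive drag model, or
integrated from per-face pressures and viscous tractions on a triangulated
surface exported by a flow solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LoadDistribution",
    "cosine_load",
    "resistive_load",
    "SurfaceStressField",
    "integrate_surface_stress",
]

RHO_WATER = 1000.0  # kg/m^3


@dataclass
class LoadDistribution:
    """Distributed loads on the (s, t) grid with a provenance tag."""

    s: np.ndarray
    t: np.ndarray
    f_x: np.ndarray  # (n_s, n_t), N/m
    f_y: np.ndarray
    m_z: np.ndarray  # N
    provenance: str = "fluid"  # fluid | muscle | fictitious | total

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.t = np.asarray(self.t, float)
        shape = (self.s.size, self.t.size)
        for name in ("f_x", "f_y", "m_z"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    def __add__(self, other: "LoadDistribution") -> "LoadDistribution":
        if not (np.array_equal(self.s, other.s) and np.array_equal(self.t, other.t)):
            raise ValueError("cannot compose loads on different grids")
        return LoadDistribution(
            s=self.s, t=self.t,
            f_x=self.f_x + other.f_x,
            f_y=self.f_y + other.f_y,
            m_z=self.m_z + other.m_z,
            provenance="total",
        )

    def rotated(self, alpha: float) -> "LoadDistribution":
        """Loads with in-plane components rotated by ``alpha`` (m_z unchanged)."""
        c, sn = np.cos(alpha), np.sin(alpha)
        return replace(self, f_x=c * self.f_x - sn * self.f_y,
                       f_y=sn * self.f_x + c * self.f_y)

    @classmethod
    def zero(cls, s, t, provenance="fluid"):
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        z = np.zeros((s.size, t.size))
        return cls(s=s, t=t, f_x=z, f_y=z.copy(), m_z=z.copy(),
                   provenance=provenance)


def cosine_load(
    amplitude_envelope: np.ndarray,
    frequency: float,
    phase: float,
    s: np.ndarray,
    t: np.ndarray,
    ramp_time: float = 0.0,
) -> LoadDistribution:
    """Lateral load ``f_y(s, t) = envelope(s) * cos(2 pi f t + phase)``.

    ``ramp_time`` applies a smooth half-cosine ramp from zero, used when the
    load drives a forward simulation started from rest.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    env = np.asarray(amplitude_envelope, float)
    if env.shape != s.shape:
        raise ValueError("envelope must be sampled on the s grid")
    carrier = np.cos(2 * np.pi * frequency * t + phase)
    if ramp_time > 0:
        carrier = carrier * ramp_factor(t, ramp_time)
    f_y = env[:, None] * carrier[None, :]
    z = np.zeros_like(f_y)
    return LoadDistribution(s=s, t=t, f_x=z, f_y=f_y, m_z=z.copy(),
                            provenance="fluid")


def ramp_factor(t, ramp_time):
    """Smooth half-cosine ramp 0 -> 1 over ``ramp_time``."""
    t = np.asarray(t, float)
    x = np.clip(t / ramp_time, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def resistive_load(kin, body, normal_coefficient: float = 2.0,
                   tangential_coefficient: float = 0.1,
                   rho_water: float = RHO_WATER) -> LoadDistribution:
    """Quadratic resistive drag stand-in for the fluid load.

    Per unit length the force opposes the local velocity, decomposed into
    components normal and tangential to the body axis:

        f = -c_n rho_w w(s) |v_n| v_n - c_t rho_w w(s) |v_t| v_t

    Larval swimming is inertia-dominated within a beat, hence the quadratic
    (rather than linear) law.  Velocities are the head-frame velocities plus
    frame motion, i.e. the full velocity relative to still water, expressed
    in the head frame.
    """
    if normal_coefficient < 0 or tangential_coefficient < 0:
        raise ValueError("resistive coefficients must be non-negative")
    v_x, v_y = kin.lab_velocity_head_components()
    th = kin.theta
    tx, ty = np.cos(th), np.sin(th)
    v_t = v_x * tx + v_y * ty
    v_n = -v_x * ty + v_y * tx
    w = body.width[:, None]
    f_t = -tangential_coefficient * rho_water * w * np.abs(v_t) * v_t
    f_n = -normal_coefficient * rho_water * w * np.abs(v_n) * v_n
    f_x = f_t * tx - f_n * ty
    f_y = f_t * ty + f_n * tx
    return LoadDistribution(s=kin.s, t=kin.t, f_x=f_x, f_y=f_y,
                            m_z=np.zeros_like(f_x), provenance="fluid")


@dataclass
class SurfaceStressField:
    """Closed triangulated surface carrying per-face pressure and viscous
    traction, with each face assigned to its nearest centreline station."""

    vertices: np.ndarray        # (n_v, 3), m
    faces: np.ndarray           # (n_f, 3) vertex indices
    pressure: np.ndarray        # (n_f,), Pa
    traction: np.ndarray        # (n_f, 3), Pa, viscous traction vector
    station: np.ndarray | None = None  # (n_f,) arc-station index

    def mesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def assign_stations(self, centreline: np.ndarray) -> None:
        """Assign every face to the nearest centreline station (centroid
        distance)."""
        m = self.mesh()
        centroids = m.triangles_center
        d2 = ((centroids[:, None, :] - centreline[None, :, :]) ** 2).sum(axis=2)
        self.station = np.argmin(d2, axis=1)


def integrate_surface_stress(
    field: SurfaceStressField,
    centreline: np.ndarray,
    s: np.ndarray,
    frame_origin: np.ndarray | None = None,
    frame_axes: np.ndarray | None = None,
    plane_normal: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate surface stresses into a per-unit-length load distribution.

    Per face, force = (-p n_hat + traction) * area.  Forces are accumulated
    per arc station, divided by the station's arc-length bin width, and the
    in-plane components are rotated into the head frame.  The distributed
    moment is taken about the local centreline point, about the deformation
    plane normal.

    Returns ``(f_x, f_y, m_z)`` sampled on ``s`` (single time instant).
    """
    mesh = field.mesh()
    if not mesh.is_watertight:
        raise ValueError("surface has boundary edges; a closed surface is required")
    if field.station is None:
        field.assign_stations(centreline)
    station = np.asarray(field.station)
    if station.min() < 0 or station.max() >= s.size:
        raise ValueError("faces assigned outside the arc grid")

    normals = mesh.face_normals          # outward unit normals
    areas = mesh.area_faces
    force = (-field.pressure[:, None] * normals + field.traction) * areas[:, None]

    if frame_origin is None:
        frame_origin = centreline[0]
    if frame_axes is None:
        ex = np.array([1.0, 0.0, 0.0])
        ey = np.array([0.0, 1.0, 0.0])
    else:
        ex, ey = frame_axes
    if plane_normal is None:
        plane_normal = np.cross(ex, ey)

    # bin widths: half-distance to neighbours
    edges = np.concatenate(([s[0]], 0.5 * (s[1:] + s[:-1]), [s[-1]]))
    widths = np.diff(edges)
    widths = np.where(widths > 0, widths, np.diff(s).mean())

    centroids = mesh.triangles_center
    lever = centroids - centreline[station]
    torque = np.cross(lever, force) @ plane_normal

    f_x = np.bincount(station, weights=force @ ex, minlength=s.size) / widths
    f_y = np.bincount(station, weights=force @ ey, minlength=s.size) / widths
    m_z = np.bincount(station, weights=torque, minlength=s.size) / widths
    return f_x, f_y, m_z
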