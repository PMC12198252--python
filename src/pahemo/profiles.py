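"""Analytic in-segment velocity fields and the parabolic inlet map.

The 0D network yields sectional flow rates only; radial structure is
reconstructed analytically.  The periodic flow in a segment is
decomposed into Fourier harmonics: the mean component carries a
Poiseuille (parabolic) profile and each oscillatory harmonic carries the
fully developed oscillatory-pipe-flow (Womersley) profile, a Bessel
function of complex argument scaled so the harmonic's sectional flow
matches its Fourier coefficient.  Superposing the harmonics reproduces
the prescribed flow to truncation accuracy.

The inlet map distributes an instantaneous flow rate over a non-circular
inlet cross-section as a parabolic-shaped profile that vanishes on the
boundary and preserves the total flow exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv
from shapely.geometry import LineString, Point, Polygon

from .geometry import VesselSegment
from .units import FluidProperties
from .waveform import FlowWaveform

__all__ = [
    "VelocityField",
    "womersley_profile",
    "sectional_flow",
    "InletVelocityMap",
    "map_inlet_velocity",
]


@dataclass
class VelocityField:
    """Axial velocity on a cross-sectional disc over one cycle.

    ``u[i, k]`` is the axial velocity (cm/s) at radius ``radii[i]`` and
    time ``times[k]``; the field is axisymmetric.
    """

    segment_id: str
    radius: float
    radii: np.ndarray
    times: np.ndarray
    u: np.ndarray = field(repr=False)
    period: float = 0.0
    mode: str = "womersley"


def _womersley_shape(alpha: float, xi: np.ndarray) -> np.ndarray:
    """Unit-flow radial profile of one oscillatory harmonic.

    ``alpha`` is the Womersley parameter of the harmonic and ``xi`` the
    normalized radius s/R.  The returned complex profile integrates to 1
    over the unit disc (2 pi \\int phi xi dxi = 1 with the pi R^2 scaling
    applied by the caller).
    """
    lam = alpha * np.exp(1j * 3.0 * np.pi / 4.0)  # i^{3/2} alpha
    j0_lam = jv(0, lam)
    numer = 1.0 - jv(0, lam * xi) / j0_lam
    denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0_lam)
    return numer / denom


def womersley_profile(
    segment: VesselSegment,
    flow: FlowWaveform,
    fluid: FluidProperties | None = None,
    n_harmonics: int = 32,
    n_radial: int = 65,
    mode: str = "womersley",
) -> VelocityField:
    """Reconstruct the axisymmetric velocity field carrying a periodic flow.

    Parameters
    ----------
    segment : VesselSegment
        Supplies the radius of the cross-section.
    flow : FlowWaveform
        Periodic sectional flow rate to be carried.
    n_harmonics : int
        Number of oscillatory Fourier harmonics retained (>= 0); the
        mean flow is always carried by a Poiseuille profile.
    mode : {"womersley", "poiseuille"}
        ``"poiseuille"`` ignores the harmonic decomposition and carries
        the instantaneous flow quasi-statically on a parabola.
    """
    if fluid is None:
        fluid = FluidProperties()
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be >= 0")
    r = segment.radius
    area = segment.area
    s = np.linspace(0.0, r, n_radial)
    xi = s / r
    t = flow.times
    q = flow.flow

    if mode == "poiseuille":
        u = (2.0 * q[None, :] / area) * (1.0 - xi[:, None] ** 2)
        return VelocityField(segment.segment_id, r, s, t, u, flow.period, "poiseuille")
    if mode != "womersley":
        raise ValueError(f"unknown mode {mode!r}")

    n = q.size
    coeffs = np.fft.rfft(q) / n
    omega = 2.0 * np.pi / flow.period
    nu = fluid.kinematic_viscosity

    u = (2.0 * coeffs[0].real / area) * (1.0 - xi**2)
    u = np.repeat(u[:, None], t.size, axis=1)
    k_max = min(n_harmonics, coeffs.size - 1)
    for k in range(1, k_max + 1):
        alpha = r * np.sqrt(k * omega / nu)
        phi = _womersley_shape(alpha, xi) / area
        # factor 2 restores the one-sided rfft amplitude
        u += np.real(2.0 * coeffs[k] * phi[:, None] * np.exp(1j * k * omega * t)[None, :])
    return VelocityField(segment.segment_id, r, s, t, u, flow.period, "womersley")


def sectional_flow(field: VelocityField) -> np.ndarray:
    """Flow rate 2 pi \\int u s ds carried by the field at each time."""
    integrand = field.u * field.radii[:, None]
    return 2.0 * np.pi * np.trapezoid(integrand, field.radii, axis=0)


@dataclass
class InletVelocityMap:
    """Velocities mapped onto inlet cross-section points at one instant."""

    points: np.ndarray  # (N, 2)
    velocities: np.ndarray  # (N,)
    weights: np.ndarray  # (N,) area weights, cm^2
    flow: float  # mL/s, exactly the mapped total

    @property
    def total_flow(self) -> float:
        return float(np.dot(self.velocities, self.weights))


def map_inlet_velocity(
    points: np.ndarray,
    boundary: np.ndarray | Polygon,
    flow_rate: float,
    weights: np.ndarray | None = None,
) -> InletVelocityMap:
    """Distribute a flow rate over a non-circular inlet as a parabolic profile.

    Each point gets a raw velocity 1 - (d / d_max)^2, where d is its
    distance from the section centroid and d_max the distance from the
    centroid to the boundary along the same ray, so the profile vanishes
    on the boundary.  The profile is then rescaled so the discrete
    surface integral (velocities dotted with the area weights, uniform
    area/N by default) equals ``flow_rate`` exactly.
    """
    polygon = boundary if isinstance(boundary, Polygon) else Polygon(np.asarray(boundary))
    if polygon.area <= 0:
        raise ValueError("inlet section has zero area")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if weights is None:
        weights = np.full(n, polygon.area / n)
    else:
        weights = np.asarray(weights, dtype=float)

    cx, cy = polygon.centroid.x, polygon.centroid.y
    span = 4.0 * max(polygon.bounds[2] - polygon.bounds[0], polygon.bounds[3] - polygon.bounds[1])
    raw = np.empty(n)
    for i, (px, py) in enumerate(pts):
        dx, dy = px - cx, py - cy
        dist = np.hypot(dx, dy)
        if dist == 0.0:
            raw[i] = 1.0
            continue
        ray = LineString([(cx, cy), (cx + dx / dist * span, cy + dy / dist * span)])
        hit = ray.intersection(polygon.exterior)
        d_max = hit.distance(Point(cx, cy)) if not hit.is_empty else dist
        if hasattr(hit, "geoms"):
            d_max = min(g.distance(Point(cx, cy)) for g in hit.geoms)
        raw[i] = max(0.0, 1.0 - (dist / d_max) ** 2)

    if flow_rate == 0.0:
        return InletVelocityMap(pts, np.zeros(n), weights, 0.0)
    discrete = float(np.dot(raw, weights))
    if discrete <= 0:
        raise ValueError("all sample points lie on or outside the boundary")
    velocities = raw * (flow_rate / discrete)
    return InletVelocityMap(pts, velocities, weights, flow_rate)
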