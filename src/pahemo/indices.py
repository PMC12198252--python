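"""Hemodynamic indices at measurement sites.

Implements the index set used to characterize pulmonary-artery flow
before and after valve implantation:

* Reynolds number Re = rho V L / mu with L the vessel diameter and V a
  cycle-averaged sectional mean speed;
* Womersley number Wo = r sqrt(2 pi / (nu T));
* vorticity index Vo: magnitude of the velocity curl, area-averaged over
  the measurement cross-section and time-averaged over the last cycle
  (units 1/s);
* energy dissipation ED: cycle-averaged total-pressure energy flux
  entering the MPA minus that leaving all outlets, reported in mW;
* regurgitation fraction PR%: backward over forward flow volume per
  cycle, with forward/backward phase-mean velocities.

Cohort summaries report the column-wise mean and sample standard
deviation, with half-up rounding to one decimal for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import MeasurementSite, PATree, measurement_site
from .network import NetworkSolution
from .profiles import VelocityField, womersley_profile
from .units import FluidProperties, erg_per_s_to_mw
from .waveform import FlowWaveform, periodic_trapezoid

__all__ = [
    "reynolds_number",
    "womersley_number",
    "vorticity_index",
    "curl_magnitude_profile",
    "energy_dissipation",
    "FlowDecomposition",
    "flow_decomposition",
    "compute_indices",
    "summarize_indices",
    "round_half_up",
]

BRANCHES = ("MPA", "RPA", "LPA")


def reynolds_number(fluid: FluidProperties, mean_velocity: float, diameter: float) -> float:
    """Re = rho V L / mu with L the vessel diameter (cm), V in cm/s."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if mean_velocity < 0:
        raise ValueError("mean velocity must be >= 0")
    return fluid.density * mean_velocity * diameter / fluid.viscosity


def womersley_number(radius: float, fluid: FluidProperties, period: float) -> float:
    """Wo = r sqrt(2 pi / (nu T)) with r in cm and T the cycle length in s."""
    if radius <= 0 or period <= 0:
        raise ValueError("radius and period must be > 0")
    return radius * math.sqrt(2.0 * math.pi / (fluid.kinematic_viscosity * period))


def curl_magnitude_profile(u: np.ndarray, radii: np.ndarray, component: str = "axial") -> np.ndarray:
    """Pointwise |curl| on a disc for an axisymmetric velocity profile.

    For an axial profile u_z(s) the only curl component is azimuthal,
    |omega| = |du/ds|.  For an azimuthal profile u_theta(s) the axial
    curl is (1/s) d(s u)/ds, evaluated at s = 0 by its limit 2 du/ds.
    """
    u = np.asarray(u, dtype=float)
    squeeze = u.ndim == 1
    if squeeze:
        u = u[:, None]
    du = np.gradient(u, radii, axis=0, edge_order=2)
    if component == "axial":
        curl = np.abs(du)
    elif component == "azimuthal":
        curl = du.copy()
        nz = radii > 0
        curl[nz, :] += u[nz, :] / radii[nz, None]
        curl[~nz, :] += du[~nz, :]  # u/s -> du/ds as s -> 0
        curl = np.abs(curl)
    else:
        raise ValueError(f"component must be 'axial' or 'azimuthal', got {component!r}")
    return curl[:, 0] if squeeze else curl


def vorticity_index(field: VelocityField, site: MeasurementSite | None = None,
                    component: str = "axial") -> float:
    """Area-weighted, time-averaged curl magnitude on the site disc (1/s).

    The pointwise curl magnitude is averaged over the cross-sectional
    disc with area weighting (2 pi s ds / pi R^2) and then averaged over
    the cycle, collapsing the curl field to one scalar per artery.
    """
    if site is not None and site.segment_id != field.segment_id:
        raise ValueError(
            f"field covers segment {field.segment_id!r}, site is on {site.segment_id!r}"
        )
    s = field.radii
    curl = curl_magnitude_profile(field.u, s, component)
    r = field.radius
    area_avg = 2.0 * np.pi * np.trapezoid(curl * s[:, None], s, axis=0) / (np.pi * r**2)
    return float(area_avg.mean())


def energy_dissipation(
    solution: NetworkSolution,
    tree: PATree,
    fluid: FluidProperties,
    outlet_pressure: str = "face",
    averaging: str = "instantaneous",
) -> float:
    """Cycle-averaged total-pressure energy loss of the pulmonary bed, in mW.

    ED = <(P + 1/2 rho V^2) A V>_MPA inlet - sum_outlets <(P + 1/2 rho V^2) A V>

    with V = Q/A the sectional mean speed and <.> the average over the
    last cycle.  ``outlet_pressure`` selects where the outlet pressure is
    taken: ``"face"`` uses the outlet boundary face (upstream of the
    Windkessel proximal resistor, matching what a 3D solve reports at
    its caps), ``"capacitor"`` uses the Windkessel storage pressure.
    ``averaging="mean_pressure"`` replaces the instantaneous P with its
    cycle mean while keeping V instantaneous — the literal reading of
    the printed formula; both coincide for steady flow.
    """
    if outlet_pressure not in ("face", "capacitor"):
        raise ValueError("outlet_pressure must be 'face' or 'capacitor'")
    if averaging not in ("instantaneous", "mean_pressure"):
        raise ValueError("averaging must be 'instantaneous' or 'mean_pressure'")
    sl = solution.last_cycle
    t = solution.times[sl]
    span = t[-1] - t[0]

    def mean_flux(p: np.ndarray, q: np.ndarray, area: float) -> float:
        v = q / area
        if averaging == "mean_pressure":
            p = np.full_like(p, np.trapezoid(p, t) / span)
        flux = (p + 0.5 * fluid.density * v**2) * area * v
        return float(np.trapezoid(flux, t) / span)

    root = tree.segment(tree.root_id)
    total = mean_flux(solution.pressures["inlet"][sl], solution.flows[tree.root_id][sl], root.area)
    for oid in tree.outlet_ids:
        if oid not in solution.flows:
            raise ValueError(f"solution is missing the trace for outlet {oid!r}")
        seg = tree.segment(oid)
        if outlet_pressure == "face":
            p = solution.pressures[oid][sl]
        else:
            p = solution.capacitor_pressures[oid][sl]
        total -= mean_flux(p, solution.flows[oid][sl], seg.area)
    return erg_per_s_to_mw(total)


@dataclass(frozen=True)
class FlowDecomposition:
    """Forward/backward split of a periodic flow at a cross-section."""

    forward_volume: float  # mL per cycle
    backward_volume: float  # mL per cycle
    forward_velocity: float  # cm/s, mean over the forward phase
    backward_velocity: float  # cm/s magnitude, mean over the backward phase
    pr_percent: float  # 100 * backward / forward


def flow_decomposition(waveform: FlowWaveform, area: float) -> FlowDecomposition:
    """Split a periodic flow into forward and backward parts.

    Forward volume integrates max(Q, 0) over the cycle and backward
    volume integrates max(-Q, 0); the regurgitation fraction PR% is 100
    times their ratio.  Phase-mean velocities average Q/A over the
    samples where the flow is in the respective direction.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    q = waveform.flow
    forward = periodic_trapezoid(np.maximum(q, 0.0), waveform.period)
    backward = periodic_trapezoid(np.maximum(-q, 0.0), waveform.period)
    if forward <= 0:
        if backward > 0:
            raise ValueError("PR%% undefined: no forward flow but nonzero backward flow")
        return FlowDecomposition(0.0, 0.0, 0.0, 0.0, 0.0)
    fwd_mask = q > 0
    bwd_mask = q < 0
    v_fwd = float(np.mean(q[fwd_mask]) / area) if fwd_mask.any() else 0.0
    v_bwd = float(np.mean(-q[bwd_mask]) / area) if bwd_mask.any() else 0.0
    return FlowDecomposition(forward, backward, v_fwd, v_bwd, 100.0 * backward / forward)


def compute_indices(
    tree: PATree,
    solution: NetworkSolution,
    fluid: FluidProperties | None = None,
    *,
    n_harmonics: int = 32,
    n_radial: int = 65,
) -> dict[str, float]:
    """Compute the per-patient index set from a solved network.

    Returns a flat mapping with per-branch Reynolds number, Womersley
    number, vorticity index, regurgitation fraction and forward/backward
    velocities, plus the whole-bed energy dissipation.  Velocity for Re
    is the cycle-averaged sectional mean speed |Q|/A at the site.
    """
    if fluid is None:
        fluid = FluidProperties()
    out: dict[str, float] = {}
    for branch in BRANCHES:
        site = measurement_site(tree, branch)
        wf = solution.segment_waveform(site.segment_id)
        mean_speed = float(np.mean(np.abs(wf.flow)) / site.area)
        out[f"{branch.lower()}_re"] = reynolds_number(fluid, mean_speed, 2.0 * site.radius)
        out[f"{branch.lower()}_wo"] = womersley_number(site.radius, fluid, wf.period)
        field = womersley_profile(
            tree.segment(site.segment_id), wf, fluid, n_harmonics=n_harmonics, n_radial=n_radial
        )
        out[f"{branch.lower()}_vo"] = vorticity_index(field, site)
        dec = flow_decomposition(wf, site.area)
        out[f"{branch.lower()}_pr"] = dec.pr_percent
        out[f"{branch.lower()}_forward_velocity"] = dec.forward_velocity
        out[f"{branch.lower()}_backward_velocity"] = dec.backward_velocity
    out["ed"] = energy_dissipation(solution, tree, fluid)
    return out


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for summary tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def summarize_indices(cohort_indices: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean and sample standard deviation of per-patient indices.

    ``cohort_indices`` has one row per patient and one numeric column per
    index; the result has rows ``"mean"`` and ``"sd"`` (n-1 denominator),
    at full precision (use :func:`round_half_up` for display).
    """
    numeric = cohort_indices.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("cohort summary needs at least two patients (sample SD undefined)")
    return pd.DataFrame(
        {"mean": numeric.mean(axis=0), "sd": numeric.std(axis=0, ddof=1)}
    ).T
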