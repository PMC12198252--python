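"""Outlet boundary conditions: resistance budgeting and RCR calibration.

The total pulmonary resistance is computed from mean pressure and flow,
split between the right and left lungs in proportion to the measured
flow distribution, and distributed over the outlets of each side by a
power law on outlet radius (Murray's law with exponent 2.3, the value
appropriate for pulmonary arteries).  Each outlet then receives a
three-element Windkessel (proximal resistance - compliance - distal
resistance).  A fixed-point calibration loop rescales the two side
blocks until the simulated right-lung flow share matches its target
within tolerance, mirroring how patient-specific simulations are tuned
to measured flow splits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import PATree
from .waveform import FlowWaveform

__all__ = [
    "WindkesselRCR",
    "ResistanceBudget",
    "CalibrationReport",
    "total_pa_resistance",
    "side_resistances",
    "murray_fractions",
    "assemble_rcr",
    "build_resistance_budget",
    "rcr_set_from_budget",
    "calibrate_flow_split",
]

_MIN_FRACTION = 1e-6


@dataclass(frozen=True)
class WindkesselRCR:
    """Three-element Windkessel outlet model (CGS units).

    proximal_resistance Rp and distal_resistance Rd in dyn.s/cm^5,
    compliance C in cm^5/dyn, distal reference pressure Pd in dyn/cm^2.
    """

    proximal_resistance: float
    compliance: float
    distal_resistance: float
    distal_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.proximal_resistance < 0:
            raise ValueError("proximal resistance must be >= 0")
        if self.distal_resistance <= 0:
            raise ValueError("distal resistance must be > 0")
        if self.compliance <= 0:
            raise ValueError("compliance must be > 0")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance


def total_pa_resistance(mean_pressure: float, mean_flow: float, distal_pressure: float = 0.0) -> float:
    """Total pulmonary resistance R = (P_mean - Pd) / Q_mean.

    All quantities CGS: pressures in dyn/cm^2, flow in mL/s; use
    :func:`pahemo.units.mmhg_to_cgs` / ``lmin_to_mls`` for clinical units.
    """
    if mean_flow <= 0:
        raise ValueError(f"mean flow must be > 0, got {mean_flow}")
    if mean_pressure <= distal_pressure:
        raise ValueError("mean pressure must exceed the distal reference pressure")
    return (mean_pressure - distal_pressure) / mean_flow


def side_resistances(r_total: float, rpa_flow_fraction: float) -> tuple[float, float]:
    """Split a total resistance into parallel RPA/LPA blocks by flow share.

    With both sides seeing the same driving pressure, a side carrying a
    fraction f of the flow has resistance R_total / f, so the parallel
    combination reproduces R_total exactly.
    """
    if r_total <= 0:
        raise ValueError("total resistance must be > 0")
    f = rpa_flow_fraction
    if not (_MIN_FRACTION < f < 1 - _MIN_FRACTION):
        raise ValueError(f"rpa_flow_fraction must lie in ({_MIN_FRACTION}, {1 - _MIN_FRACTION}), got {f}")
    return r_total / f, r_total / (1.0 - f)


def murray_fractions(outlet_areas, exponent: float = 2.3) -> np.ndarray:
    """Flow fractions from outlet cap areas via Murray's law Q ~ r^exponent.

    Cap areas are converted to effective radii r = sqrt(A/pi) before the
    power-law weighting; fractions sum to 1.
    """
    areas = np.asarray(outlet_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("outlet_areas must be non-empty")
    if np.any(areas <= 0):
        raise ValueError("all outlet areas must be > 0")
    if exponent <= 0:
        raise ValueError("Murray exponent must be > 0")
    radii = np.sqrt(areas / math.pi)
    weights = radii**exponent
    return weights / weights.sum()


def assemble_rcr(
    outlet_resistance: float,
    proximal_fraction: float = 0.1,
    time_constant: float = 1.0,
    distal_pressure: float = 0.0,
) -> WindkesselRCR:
    """Build a three-element Windkessel from an outlet's total resistance.

    Rp = proximal_fraction * R, Rd = (1 - proximal_fraction) * R, and the
    compliance is set from the washout time constant tau = Rd * C.  The
    default tau of 1.0 s is a typical pulmonary Windkessel time constant;
    the clinical source this pipeline emulates does not report Rp:Rd or C,
    so both knobs are exposed.
    """
    if outlet_resistance <= 0:
        raise ValueError("outlet resistance must be > 0")
    if not 0 <= proximal_fraction < 1:
        raise ValueError("proximal_fraction must lie in [0, 1)")
    if time_constant <= 0:
        raise ValueError("time_constant must be > 0")
    rp = proximal_fraction * outlet_resistance
    rd = (1.0 - proximal_fraction) * outlet_resistance
    return WindkesselRCR(rp, time_constant / rd, rd, distal_pressure)


@dataclass(frozen=True)
class ResistanceBudget:
    """Distribution of the total resistance over the tree's outlets."""

    r_total: float
    rpa_fraction: float
    outlet_resistances: dict[str, float]  # outlet segment id -> R (dyn.s/cm^5)
    sides: dict[str, str] = field(repr=False)  # outlet id -> "RPA" | "LPA"
    murray_exponent: float = 2.3

    def __post_init__(self) -> None:
        if not self.outlet_resistances:
            raise ValueError("budget has no outlets")
        par = 1.0 / sum(1.0 / r for r in self.outlet_resistances.values())
        if not math.isclose(par, self.r_total, rel_tol=1e-9):
            raise ValueError(
                f"parallel combination of outlet resistances ({par:.6g}) does not "
                f"reproduce R_total ({self.r_total:.6g})"
            )

    @property
    def lpa_fraction(self) -> float:
        return 1.0 - self.rpa_fraction

    def side_ids(self, side: str) -> list[str]:
        return [oid for oid, s in self.sides.items() if s == side]

    def side_parallel_resistance(self, side: str) -> float:
        ids = self.side_ids(side)
        return 1.0 / sum(1.0 / self.outlet_resistances[oid] for oid in ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "r_total": self.r_total,
                "rpa_fraction": self.rpa_fraction,
                "murray_exponent": self.murray_exponent,
                "outlets": {
                    oid: {"resistance": self.outlet_resistances[oid], "side": self.sides[oid]}
                    for oid in sorted(self.outlet_resistances)
                },
            },
            indent=2,
            sort_keys=True,
        )


def build_resistance_budget(
    tree: PATree,
    r_total: float,
    rpa_flow_fraction: float,
    murray_exponent: float = 2.3,
) -> ResistanceBudget:
    """Assemble the per-outlet resistance budget for a tree.

    The total resistance is split between sides by flow share, then each
    side's resistance is distributed over its outlets in inverse
    proportion to their Murray flow fractions (parallel resistors:
    R_i = R_side / f_i).
    """
    r_rpa, r_lpa = side_resistances(r_total, rpa_flow_fraction)
    resistances: dict[str, float] = {}
    sides: dict[str, str] = {}
    for side, r_side in (("RPA", r_rpa), ("LPA", r_lpa)):
        ids = tree.side_outlets(side)
        if not ids:
            raise ValueError(f"tree has no outlets on side {side}")
        areas = [tree.segment(oid).area for oid in ids]
        fracs = murray_fractions(areas, murray_exponent)
        for oid, f in zip(ids, fracs):
            resistances[oid] = r_side / float(f)
            sides[oid] = side
    return ResistanceBudget(r_total, rpa_flow_fraction, resistances, sides, murray_exponent)


def rcr_set_from_budget(
    budget: ResistanceBudget,
    proximal_fraction: float = 0.1,
    time_constant: float = 1.0,
    distal_pressure: float = 0.0,
) -> dict[str, WindkesselRCR]:
    return {
        oid: assemble_rcr(r, proximal_fraction, time_constant, distal_pressure)
        for oid, r in budget.outlet_resistances.items()
    }


@dataclass
class CalibrationReport:
    """Trace of the flow-split calibration loop."""

    target_rpa_fraction: float
    tolerance: float
    iterations: int
    achieved_fractions: list[float]
    final_relative_error: float
    converged: bool

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _achieved_rpa_fraction(tree: PATree, solution, budget: ResistanceBudget) -> float:
    last = solution.last_cycle
    vol = {oid: float(np.trapezoid(solution.flows[oid][last], solution.times[last]))
           for oid in budget.outlet_resistances}
    rpa = sum(vol[oid] for oid in budget.side_ids("RPA"))
    total = sum(vol.values())
    return rpa / total


def calibrate_flow_split(
    tree: PATree,
    budget: ResistanceBudget,
    inflow: FlowWaveform,
    target_rpa_fraction: float,
    tolerance: float = 0.10,
    max_iter: int = 20,
    *,
    fluid=None,
    proximal_fraction: float = 0.1,
    time_constant: float = 1.0,
    distal_pressure: float = 0.0,
    n_cycles: int = 6,
    steps_per_cycle: int = 256,
) -> tuple[ResistanceBudget, CalibrationReport]:
    """Tune side resistances until the simulated RPA flow share hits target.

    Each iteration solves the pulsatile network, measures the last-cycle
    RPA share of outlet volume, and — if the relative error exceeds
    ``tolerance`` — multiplicatively rescales the RPA outlet block by
    (achieved / target) and the LPA block by the complementary ratio,
    then renormalizes all outlets by a common factor so the total
    parallel resistance is preserved.  The relative error is
    |achieved - target| / target, matching the usual "within 10%"
    flow-split criterion read as a relative bound.

    Returns the (possibly updated) budget and a report; exhaustion of
    ``max_iter`` yields a non-converged report rather than an exception.
    """
    from .network import solve_network  # deferred to avoid an import cycle
    from .units import FluidProperties

    if not 0 < target_rpa_fraction < 1:
        raise ValueError("target_rpa_fraction must lie in (0, 1)")
    if fluid is None:
        fluid = FluidProperties()

    achieved_trace: list[float] = []
    current = budget
    for iteration in range(max_iter + 1):
        rcrs = rcr_set_from_budget(current, proximal_fraction, time_constant, distal_pressure)
        solution = solve_network(tree, rcrs, inflow, fluid, n_cycles=n_cycles,
                                 steps_per_cycle=steps_per_cycle)
        achieved = _achieved_rpa_fraction(tree, solution, current)
        achieved_trace.append(achieved)
        error = abs(achieved - target_rpa_fraction) / target_rpa_fraction
        if error <= tolerance:
            report = CalibrationReport(target_rpa_fraction, tolerance, iteration,
                                       achieved_trace, error, True)
            return current, report
        if iteration == max_iter:
            break
        factor_rpa = achieved / target_rpa_fraction
        factor_lpa = (1.0 - achieved) / (1.0 - target_rpa_fraction)
        scaled = {}
        for oid, r in current.outlet_resistances.items():
            scaled[oid] = r * (factor_rpa if current.sides[oid] == "RPA" else factor_lpa)
        par = 1.0 / sum(1.0 / r for r in scaled.values())
        norm = current.r_total / par
        scaled = {oid: r * norm for oid, r in scaled.items()}
        new_rpa_fraction = current.r_total / (1.0 / sum(
            1.0 / scaled[oid] for oid in current.side_ids("RPA")))
        current = ResistanceBudget(current.r_total, new_rpa_fraction, scaled,
                                   dict(current.sides), current.murray_exponent)

    report = CalibrationReport(target_rpa_fraction, tolerance, max_iter,
                               achieved_trace, error, False)
    return current, report
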