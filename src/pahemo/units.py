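"""Unit conversions and fluid constants.

Everything internal is CGS (cm, g, s): pressures in dyn/cm^2, flows in
mL/s, resistances in dyn.s/cm^5, compliances in cm^5/dyn.  Clinical units
(mmHg, L/min) are accepted only at I/O boundaries through the converters
below.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 1 mmHg in dyn/cm^2
MMHG_TO_DYN_CM2 = 1333.22

#: 1 mW in erg/s
MW_TO_ERG_PER_S = 1.0e4


def mmhg_to_cgs(pressure_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return pressure_mmhg * MMHG_TO_DYN_CM2


def cgs_to_mmhg(pressure_dyn_cm2: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return pressure_dyn_cm2 / MMHG_TO_DYN_CM2


def lmin_to_mls(flow_l_min: float) -> float:
    """Convert a volumetric flow from L/min to mL/s."""
    return flow_l_min * 1000.0 / 60.0


def erg_per_s_to_mw(power_erg_s: float) -> float:
    """Convert a power from erg/s to mW."""
    return power_erg_s / MW_TO_ERG_PER_S


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology for the rigid-wall Newtonian model.

    Parameters
    ----------
    density : float
        Fluid density rho in g/cm^3.  Default 1.06 (whole blood).
    viscosity : float
        Dynamic viscosity mu in g/(cm.s) = poise.  Default 0.04.
    """

    density: float = 1.06
    viscosity: float = 0.04

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in cm^2/s."""
        return self.viscosity / self.density
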