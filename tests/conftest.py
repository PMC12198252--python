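import numpy as np
import pytest

from pahemo import FluidProperties, FlowWaveform
from pahemo.geometry import PATree, VesselSegment


@pytest.fixture
def fluid():
    return FluidProperties()


@pytest.fixture
def minimal_tree():
    """MPA plus two principal segments that are themselves the outlets.

    The side radius r = 1/sqrt(2) makes the two outlet areas sum exactly
    to the MPA area, so kinetic-energy fluxes cancel between inlet and
    outlets (the uniform-total-cross-section configuration).
    """
    r_side = 1.0 / np.sqrt(2.0)
    return PATree(
        [
            VesselSegment("MPA", None, 1.0, 2.0),
            VesselSegment("RPA", "MPA", r_side, 3.0),
            VesselSegment("LPA", "MPA", r_side, 3.0),
        ]
    )


@pytest.fixture
def constant_inflow():
    return FlowWaveform(period=1.0, flow=np.full(64, 10.0))
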