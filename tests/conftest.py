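"""Shared fixtures: unit spaces, cell drivers and a default closed loop.

The tension/circulation fixtures are session-scoped because building the
paced transients and integrating the loop are the costly steps shared by
many tests.
"""

import numpy as np
import pytest

from cardiogsa import cell_and_passive as cp
from cardiogsa import circulation as circ
from cardiogsa.parameter_space import ParameterSpace, space_from_table

BCL = 854.0
ACTIVATION = {
    "LA": (0.0, 80.0), "RA": (0.0, 80.0),
    "LV": (150.0, 90.0), "RV": (150.0, 90.0),
}


def unit_space(d: int, lo: float = 0.0, hi: float = 1.0) -> ParameterSpace:
    return space_from_table(
        [{"name": f"x{i+1}", "role": "free", "bounds": [lo, hi]}
         for i in range(d)]
    )


@pytest.fixture(scope="session")
def vent_driver():
    ca = cp.simulate_calcium(cp.CalciumParams(), BCL, n_beats=4)
    return cp.simulate_tension(ca, cp.LandParams(), dt=0.05)


@pytest.fixture(scope="session")
def atrial_driver():
    ca = cp.simulate_calcium(cp.ATRIAL_CALCIUM, BCL, n_beats=4)
    return cp.simulate_tension(ca, cp.ATRIAL_LAND, dt=0.05)


@pytest.fixture(scope="session")
def drivers(vent_driver, atrial_driver):
    return {"LV": vent_driver, "RV": vent_driver,
            "LA": atrial_driver, "RA": atrial_driver}


@pytest.fixture(scope="session")
def default_trace(drivers):
    """Default closed-loop run (8 beats) and its feature dictionary."""
    params = circ.CircParams()
    cir = circ.build_circuit(params, None, drivers, ACTIVATION)
    trace = circ.run_beats(cir, n_beats=8, dt=1.0, substep=1.0)
    feats = circ.pv_features(trace, ACTIVATION)
    return trace, feats
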