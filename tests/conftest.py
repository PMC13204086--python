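"""Shared fixtures: small synthetic phantoms and beam geometry."""

import numpy as np
import pytest

from dcsplan import BeamGeometry, MachineModel, build_synthetic_phantom
from dcsplan.geometry import build_dose_grid


@pytest.fixture(scope="session")
def sphere_phantom():
    """80 mm water box, 2 mm grid, 15 mm spherical target + auto ring."""
    return build_synthetic_phantom(
        {
            "grid": {"size_mm": [80.0, 80.0, 80.0], "spacing": 2.0},
            "density": 1.0,
            "seed": 0,
            "structures": [
                {
                    "name": "target",
                    "role": "target",
                    "shape": {"type": "sphere", "center": [0.0, 0.0, 0.0], "radius": 15.0},
                }
            ],
            "ring_mm": 10.0,
        }
    )


@pytest.fixture(scope="session")
def sphere_grid(sphere_phantom):
    return build_dose_grid(sphere_phantom)


@pytest.fixture(scope="session")
def beam():
    return BeamGeometry()


@pytest.fixture(scope="session")
def machine():
    return MachineModel()
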