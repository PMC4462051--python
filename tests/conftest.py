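import numpy as np
import pytest

from capsim.flow import FluidProperties, solve_flow
from capsim.geometry import VesselGeometry
from capsim.mesh import build_mesh


@pytest.fixture(scope="session")
def geom():
    return VesselGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def acellular_field(geom, fluid):
    """Coarse acellular Stokes solution shared across tests."""
    mesh = build_mesh(geom, [], n_r=16, n_z=80)
    return solve_flow(mesh, fluid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
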