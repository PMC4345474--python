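import numpy as np
import pytest

from meshlift.mesh import DomainGeometry, build_annulus_mesh, build_hierarchy
from meshlift.transport import SolverSettings, TransportParameters, solve_transient


@pytest.fixture(scope="session")
def geometry():
    return DomainGeometry()


@pytest.fixture(scope="session")
def params():
    return TransportParameters()


@pytest.fixture(scope="session")
def small_mesh(geometry):
    """~200-element annulus used by feature/operator tests."""
    return build_annulus_mesh(geometry, 200, seed=3)


@pytest.fixture(scope="session")
def small_hierarchy(geometry):
    """Tiny nested hierarchy (L0..L3) for refinement and feature tests."""
    return build_hierarchy(geometry, 120, 3, seed=7)


@pytest.fixture(scope="session")
def solved_small(small_mesh, params):
    """Balloon solution at 1 h on the small mesh (shared across tests)."""
    return solve_transient(small_mesh, params, SolverSettings())
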