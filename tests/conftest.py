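import numpy as np
import pytest

from rbcmesh import (AffineDeformation, RBCGeometry, discocyte_surface,
                     make_fixture, mesh_surface, transformed_surface)


@pytest.fixture(scope="session")
def geometry():
    return RBCGeometry()


@pytest.fixture(scope="session")
def surface(geometry):
    return discocyte_surface(geometry)


@pytest.fixture(scope="session")
def rbc_mesh_12k(surface):
    """Relaxed discocyte at ~12,000 edges (fast; used by most tests)."""
    return mesh_surface(surface, target_edges=12_000)


@pytest.fixture(scope="session")
def rbc_mesh_16k(surface):
    """Finer relaxed mesh (>10,000 faces) for estimator-comparison tests."""
    return mesh_surface(surface, target_edges=16_000)


@pytest.fixture(scope="session")
def rbc_mesh_121k(surface):
    """Relaxed discocyte at the spectrin-network edge count (~121,000)."""
    return mesh_surface(surface, target_edges=121_000)


@pytest.fixture(scope="session")
def strained_surface_45_175(surface):
    return transformed_surface(surface, AffineDeformation(45.0, 1.75))


@pytest.fixture(scope="session")
def sphere():
    return make_fixture("sphere", r=1.0)


@pytest.fixture(scope="session")
def sphere_mesh(sphere):
    return mesh_surface(sphere, target_edges=3_000)


@pytest.fixture(scope="session")
def ellipsoid():
    return make_fixture("ellipsoid", a=2.0, b=1.0, c=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
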