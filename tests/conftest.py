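"""Shared fixtures: small phantoms, meshes and RF frame pairs.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive artifacts (meshes, RF simulations) shared across tests.
"""

import numpy as np
import pytest

from plaquemech import phantom
from plaquemech.fem import mesh_geometry
from plaquemech.ultrasound import FieldOfView, simulate_rf


@pytest.fixture(scope="session")
def concentric_geometry():
    """Concentric plaque: lumen 1.5 mm, intima 1.25 mm, wall 0.5 mm.

    The tissue column through the center is 2 x 1.75 mm = 3.5 mm.
    """
    return phantom.make_vessel_geometry(1.5, 0.5, 1.25, 0.0,
                                        n_vertices=96, center=(0.0, 5.0))


@pytest.fixture(scope="session")
def eccentric_geometry():
    return phantom.make_vessel_geometry(1.5, 0.5, 2.0, 0.6,
                                        n_vertices=128, center=(0.0, 6.0), seed=5)


@pytest.fixture(scope="session")
def concentric_mesh(concentric_geometry):
    return mesh_geometry(concentric_geometry, target_edge=0.25)


@pytest.fixture(scope="session")
def small_geometry():
    """Small vessel for fast RF simulation fixtures."""
    return phantom.make_vessel_geometry(1.0, 0.4, 0.6, 0.0,
                                        n_vertices=64, center=(0.0, 3.0))


@pytest.fixture(scope="session")
def small_fov():
    return FieldOfView(-2.0, 2.0, 6.0)


@pytest.fixture(scope="session")
def small_scatterers(small_geometry):
    return phantom.make_scatterers(small_geometry, 3000.0, seed=21)


@pytest.fixture(scope="session")
def small_rf(small_scatterers, small_fov):
    """One noiseless RF frame of the small phantom."""
    return simulate_rf(small_scatterers, field_of_view=small_fov)


@pytest.fixture(scope="session")
def tissue_roi():
    """ROI strictly inside the small phantom's upper tissue band, far
    enough from the lumen and bath that no template straddles an anechoic
    boundary."""
    return (-0.5, 0.5, 1.25, 1.95)
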