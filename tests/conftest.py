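"""Shared small fixtures: a tiny fan-beam system, partition, and spectrum."""
import numpy as np
import pytest

import polybasis as pb
from polybasis.forward_model import PolyForwardModel


@pytest.fixture(scope="session")
def tiny_geometry():
    return pb.FanBeamGeometry(
        sor=10.0, sod=15.0, detector_kind="linear",
        n_bins=12, bin_size=0.6, n_views=10, nx=8, ny=8, pixel_size=0.5,
    )


@pytest.fixture(scope="session")
def tiny_op(tiny_geometry):
    return pb.build_projector(tiny_geometry)


@pytest.fixture(scope="session")
def tiny_grid():
    return pb.EnergyGrid(np.array([40.0, 60.0, 80.0]))


@pytest.fixture(scope="session")
def tiny_materials(tiny_grid):
    mats = tuple(
        pb.load_fixture_material(n)
        for n in ("water", "bone_cortical", "iodine_solution_20mgml")
    )
    return pb.MaterialSet(mats, tiny_grid)


@pytest.fixture(scope="session")
def tiny_partition():
    # 8x8 image, three regions: water-bone ring, water-iodine core, water rim
    labels = np.ones((8, 8), dtype=np.int32)
    labels[2:6, 2:6] = 2
    labels[3:5, 3:5] = 3
    phi = ((0, 1), (0, 2), (0,))
    psi_vc = (0, 1)
    return pb.validate_partition(labels, phi, psi_vc, K=3)


@pytest.fixture(scope="session")
def tiny_spectrum(tiny_grid):
    return pb.normalize_spectrum(np.array([0.3, 0.5, 0.2]), tiny_grid)


@pytest.fixture(scope="session")
def tiny_model(tiny_op, tiny_partition, tiny_spectrum, tiny_materials):
    return PolyForwardModel(tiny_op, tiny_partition, tiny_spectrum, tiny_materials)
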