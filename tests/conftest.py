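import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrplanqa.grid import StructureMask, StructureSet, VoxelGrid
from mrplanqa.phantom import (
    build_phantom,
    default_spec,
    prescriptions_from_spec,
    simulate_base_dose,
)
from mrplanqa.structures import derive_standard_regions

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom with all derived evaluation regions."""
    structs = build_phantom(default_spec())
    derive_standard_regions(structs)
    return structs


@pytest.fixture(scope="session")
def default_rx():
    return prescriptions_from_spec(default_spec())


@pytest.fixture(scope="session")
def default_rx_gy(default_rx):
    return {k: p.total_dose_Gy for k, p in default_rx.items()}


@pytest.fixture(scope="session")
def b0_dose(default_phantom, default_rx):
    """One noisy baseline (0 T) plan on the default phantom."""
    return simulate_base_dose(default_phantom, default_rx, seed=1234)


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), name="m"):
    voxels = np.asarray(voxels, dtype=bool)
    return StructureMask(name, VoxelGrid(voxels.shape, spacing), voxels)


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0), name="sphere"):
    grid = VoxelGrid(shape, spacing)
    X, Y, Z = grid.meshgrid()
    voxels = (
        (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        <= radius**2
    )
    return StructureMask(name, grid, voxels)
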