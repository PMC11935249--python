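import numpy as np
import pytest
from scipy import sparse

from letimpt import (DensityMap, PhantomConfig, PhysicsTables, Scenario, Spot,
                     StructureSet, VoxelGrid, build_phantom)
from letimpt.planning import InfluenceSet


@pytest.fixture(scope="session")
def tables():
    return PhysicsTables()


@pytest.fixture(scope="session")
def nominal():
    return Scenario()


def make_water_box(dims=(48, 32, 32), spacing=2.5):
    sp = (spacing,) * 3
    grid = VoxelGrid(dims, sp, tuple(-(d - 1) * s / 2 for d, s in zip(dims, sp)))
    return grid, DensityMap(grid, np.ones(dims))


@pytest.fixture(scope="session")
def water_box():
    return make_water_box()


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """Small, fast phantom sharing the default anatomy proportions."""
    return PhantomConfig(
        dims=(40, 40, 20), spacing_mm=(4.0, 4.0, 4.0),
        body_semiaxes_mm=(70.0, 60.0), ctv_semiaxes_mm=(14.0, 12.0, 12.0),
        bladder_semiaxes_mm=(18.0, 14.0, 14.0), rectum_length_mm=60.0,
        bone_semiaxes_mm=(12.0, 20.0, 30.0),
    )


def toy_influence(n_vox=10, n_spots=5, seed=0, with_let=True, scenarios=None):
    """Dense random instance wrapped as an InfluenceSet on an (n,1,1) grid."""
    rng = np.random.default_rng(seed)
    grid = VoxelGrid((n_vox, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    scenarios = scenarios or [Scenario()]
    matrices = {}
    for i, sc in enumerate(scenarios):
        d = rng.uniform(0.5, 2.0, size=(n_vox, n_spots))
        matrices[sc.label] = sparse.csc_matrix(d * (1.0 + 0.05 * i))
    let = None
    if with_let:
        lets = rng.uniform(1.0, 8.0, size=(n_vox, n_spots))
        let = sparse.csc_matrix(matrices["nominal"].toarray() * lets)
    spots = [Spot(0, 100.0, 0.0, 0.0, j) for j in range(n_spots)]
    inf = InfluenceSet(
        engine="mc" if with_let else "pb", spots=spots, beams=[], grid=grid,
        scenarios=list(scenarios), matrices=matrices,
        row_subsets={sc.label: None for sc in scenarios}, dose_let=let,
    )
    return inf, grid


def toy_structures(grid, names=("ctv",)):
    """All-voxel masks for the toy grid."""
    masks = {n: np.ones(grid.dims, bool) for n in names}
    return StructureSet(grid, masks)
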