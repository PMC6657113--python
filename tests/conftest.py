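import numpy as np
import pytest

import ventriflow as vf
from ventriflow import phantom


@pytest.fixture
def small_grid():
    """20^3 grid at 2 mm isotropic, one phase: full-grid volume 64 mL."""
    return vf.VoxelGrid(20, 20, 20, 2.0, 2.0, 2.0, nt=1)


def poiseuille_grid(n: int, nt: int = 1) -> vf.VoxelGrid:
    """Grid for the reference pipe (R = 10 mm, L = 50 mm): the cylinder wall
    falls exactly on the outermost voxel-center ring, so the discretization
    error is dominated by the systematic one-sided wall stencil and shrinks
    monotonically under refinement."""
    return vf.VoxelGrid(n, n, n, 20.0 / (n - 1), 20.0 / (n - 1), 51.2 / (n - 1), nt=nt)


@pytest.fixture
def poiseuille_64():
    grid = poiseuille_grid(64)
    fld, mask = phantom.make_poiseuille(grid, 10.0, 50.0, 1.0)
    return fld, mask


def random_field_and_mask(seed: int, shape=(8, 8, 8), nt: int = 2, spacing=(1.5, 2.0, 1.0)):
    """Small random velocity field with a random (non-trivial) mask."""
    rng = np.random.default_rng(seed)
    grid = vf.VoxelGrid(*shape, *spacing, nt=nt)
    v = rng.normal(0.0, 0.4, (*shape, nt, 3))
    m = (rng.random((*shape, nt)) < 0.7).astype(np.uint8)
    return vf.VelocityField(grid, v, venc=1.5), vf.SegmentationMask(grid, m)
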