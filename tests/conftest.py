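import numpy as np
import pytest

from cervixadapt import (Mask, PenumbraParams, Prescription, VoxelGrid,
                         default_grid, make_patient)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """5 mm grid over the same pelvic volume; fast renders for strategy tests."""
    n, sp = 80, 5.0
    half = (n - 1) / 2.0 * sp
    return VoxelGrid((n, n, n), (sp, sp, sp), (-half, -half, -half))


@pytest.fixture(scope="session")
def template():
    return make_patient(1)


@pytest.fixture(scope="session")
def rx():
    return Prescription()


@pytest.fixture(scope="session")
def pen():
    return PenumbraParams(sigma=6.0, shoulder=2.5, max_hotspot=1.04)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_grid(n=24, spacing=1.0):
    return VoxelGrid((n, n, n), (spacing,) * 3, (0.0, 0.0, 0.0))


def random_mask(rng, grid, p=0.05, ensure_nonempty=True):
    data = rng.random(grid.shape) < p
    if ensure_nonempty and not data.any():
        data[tuple(d // 2 for d in grid.shape)] = True
    return Mask(grid, data)
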