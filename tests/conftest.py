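import numpy as np
import pytest

from cardiogrid.geometry import GeometryGrid, make_box


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_box():
    return make_box(6, 6, 1, h=0.5)


def random_geometry(rng, max_n=8, three_d=True, p_tissue=0.7):
    """Random irregular geometry with normalized random fibres."""
    nx = int(rng.integers(3, max_n))
    ny = int(rng.integers(3, max_n))
    nz = int(rng.integers(3, max_n)) if three_d else 1
    status = (rng.random((nx, ny, nz)) < p_tissue).astype(np.int32)
    if status.sum() == 0:
        status[nx // 2, ny // 2, nz // 2] = 1
    fibre = rng.normal(size=(nx, ny, nz, 3))
    norms = np.linalg.norm(fibre, axis=-1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    fibre = fibre / norms
    return GeometryGrid(nx, ny, nz, float(rng.uniform(0.2, 1.5)), status, fibre)
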