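import numpy as np
import pytest

from sourcetf.forward import (
    HeadSphere,
    build_leadfield,
    build_source_grid,
    make_cap_montage,
)
from sourcetf.inverse import build_inverse


@pytest.fixture(scope="session")
def sphere():
    return HeadSphere(radius_mm=90.0, conductivity=0.33)


@pytest.fixture(scope="session")
def montage32(sphere):
    return make_cap_montage(32, sphere)


@pytest.fixture(scope="session")
def grid20(sphere):
    """Coarse source grid: 20-mm spacing inside a 70-mm sphere (179 voxels)."""
    return build_source_grid(("sphere", 70.0), 20.0)


@pytest.fixture(scope="session")
def leadfield32(montage32, grid20, sphere):
    return build_leadfield(montage32, grid20, sphere)


@pytest.fixture(scope="session")
def inverse_op(leadfield32):
    return build_inverse(leadfield32, snr=3.0)


@pytest.fixture(scope="session")
def tiny_leadfield(sphere):
    """5 collinear voxels x 8 channels — for literal-loop oracle checks."""
    montage = make_cap_montage(8, sphere)
    grid = build_source_grid(("box", [-40.0, 0.0, 20.0], [40.0, 0.0, 20.0]), 20.0)
    return build_leadfield(montage, grid, sphere)
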