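import numpy as np
import pytest

from calciscan.fixtures import (
    load_packaged_ct_table,
    load_packaged_isotope_table,
)
from calciscan.phantom import ShellGeometry, make_shell_phantom


@pytest.fixture(scope="session")
def ct_table():
    return load_packaged_ct_table()


@pytest.fixture(scope="session")
def isotope_table():
    return load_packaged_isotope_table()


@pytest.fixture(scope="session")
def hollow_sphere():
    """Single-chamber phantom: outer radius 14 um, wall 4 um, 0.8 um/voxel."""
    geom = ShellGeometry(n_chambers=1, first_radius_um=14.0, wall_um=4.0)
    return make_shell_phantom(geom, seed=0, voxel_size=0.8, grid=48)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
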