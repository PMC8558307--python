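"""Shared fixtures: small grids and phantoms sized for fast unit tests."""

import numpy as np
import pytest

from headmorph import PhantomSpec, VolumeImage, make_phantom
from headmorph.dispfield import DisplacementField


@pytest.fixture
def unit_grid():
    """A 10^3 grid, 1 mm isotropic, origin at voxel (0,0,0)."""
    return VolumeImage(data=np.zeros((10, 10, 10)), affine=np.eye(4))


@pytest.fixture
def coarse_spec():
    """Phantom on a 32^3 grid at 4 mm: same head geometry, fast to register."""
    return PhantomSpec(shape=(32, 32, 32), spacing=4.0)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64^3 baseline phantom, built once per session."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def baseline_mesh_with_parts():
    """The default 16^3-element brain mesh with GM/WM/LV parts assigned."""
    from headmorph import make_baseline_hexmesh

    return make_baseline_hexmesh(PhantomSpec())


def make_field(fn, shape=(12, 12, 12), spacing=1.0, origin=None, tag="f"):
    """Displacement field from a world-coordinate function u(x)."""
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    if origin is None:
        origin = -spacing * (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = origin
    ref = VolumeImage(data=np.zeros(shape), affine=aff)
    xyz = ref.grid_world_coords()
    return DisplacementField(vectors=fn(xyz), affine=aff, tag=tag)


@pytest.fixture
def field_factory():
    return make_field
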