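import numpy as np
import pytest
import trimesh

from cranioreg.phantom import PhantomSpec, build_phantom
from cranioreg.surface import TriMesh, extract_isosurface

# Coarse (1.6 mm voxel) noiseless phantom: same anatomy at quarter the voxel
# count; enough for registration contracts while keeping the suite fast.
COARSE_KW = dict(
    voxel_size_mm=1.6,
    grid_shape=(68, 71, 53),
    noise_sd_hu=0.0,
    bias_field_amp_hu=0.0,
)


@pytest.fixture(scope="session")
def coarse_spec():
    return PhantomSpec(seed=7, **COARSE_KW)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    return build_phantom(coarse_spec)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_phantom):
    vol, _, _ = coarse_phantom
    return extract_isosurface(vol, 500.0)


@pytest.fixture(scope="session")
def fine_phantom():
    """Default-resolution (0.8 mm) noiseless phantom for geometry checks."""
    spec = PhantomSpec(seed=11, noise_sd_hu=0.0, bias_field_amp_hu=0.0)
    vol, truth, atlas = build_phantom(spec)
    return spec, vol, truth, atlas


@pytest.fixture(scope="session")
def fine_mesh(fine_phantom):
    _, vol, _, _ = fine_phantom
    return extract_isosurface(vol, 500.0)


@pytest.fixture(scope="session")
def icosphere_mesh():
    ts = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    return TriMesh(np.asarray(ts.vertices), np.asarray(ts.faces))


def make_plate(nx=20, ny=20, pitch=1.0, z=0.0):
    """Flat rectangular plate in the z-plane, upward normals."""
    xs = np.arange(nx + 1) * pitch
    ys = np.arange(ny + 1) * pitch
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return TriMesh(verts, np.array(faces))


@pytest.fixture
def plate():
    return make_plate()
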