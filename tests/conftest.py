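import numpy as np
import pytest

from nestkin.simulate import FlowSimConfig, SubsetSpec, VolumeSimConfig
from nestkin.volumes import ImageVolume


def render_sphere_volume(
    shape_um=(60.0, 60.0, 60.0),
    voxel=(1.0, 1.0, 5.0),
    centers=((30.0, 30.0, 30.0),),
    radius=10.0,
    value=100.0,
    channel="eGFP",
) -> ImageVolume:
    """Rasterize solid spheres on an anisotropic grid (voxel centres at
    (i + 0.5) * voxel size), independently of the package's renderer."""
    dx, dy, dz = voxel
    nx, ny, nz = (int(round(s / v)) for s, v in zip(shape_um, voxel))
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    grid = np.zeros((nz, ny, nx), dtype=np.float32)
    for cx, cy, cz in centers:
        mask = (
            (zs[:, None, None] - cz) ** 2
            + (ys[None, :, None] - cy) ** 2
            + (xs[None, None, :] - cx) ** 2
        ) <= radius**2
        grid[mask] = value
    return ImageVolume(grid, voxel, channel)


@pytest.fixture
def small_volume_config():
    """A quick-to-render planted-nest configuration for unit tests."""
    return VolumeSimConfig(
        volume_shape_um=(300.0, 300.0, 150.0),
        n_tubules=5,
        n_nests_per_class={"Bright": 3, "Mid": 2},
        nest_size_distribution=4,
        n_singletons=4,
        n_autofluor_blobs=2,
    )


@pytest.fixture
def flow_config():
    subsets = {
        "P3": {
            "Bright": SubsetSpec(300, s_g2_m_fraction=0.5, kit_fraction=0.01),
            "Mid": SubsetSpec(400, s_g2_m_fraction=0.3, kit_fraction=0.06),
            "Dim": SubsetSpec(600, kit_fraction=0.25),
            "eGFPneg": SubsetSpec(700, kit_fraction=0.10),
            "nongerm": SubsetSpec(500),
        }
    }
    return FlowSimConfig(ages=["P3"], subsets=subsets)
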