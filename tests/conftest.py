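import numpy as np
import pytest

from mealscan import (
    DEFAULT_INTRINSICS,
    PointCloud,
    SceneSpec,
    crop_to_disk,
    depth_to_cloud,
    render_depth,
)
from mealscan.synthetic import MoundSpec, PlateSpec


@pytest.fixture(scope="session")
def intrinsics():
    return DEFAULT_INTRINSICS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_scene(mounds, noise_sigma=0.0, seed=1, plate_radius=0.09):
    return SceneSpec(
        table_depth=0.5,
        plates=[PlateSpec(center=(0.0, 0.0), radius=plate_radius)],
        mounds=mounds,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mound_scene():
    """One plate with a single tall mound, noise-free."""
    return make_scene([MoundSpec("m", 0, (0.0, 0.0), a=0.03, h=0.03)])


@pytest.fixture(scope="session")
def mound_crop(mound_scene, intrinsics):
    """Cropped per-plate cloud of the mound scene plus its label raster."""
    frame, labels = render_depth(mound_scene, intrinsics, return_labels=True)
    cloud = crop_to_disk(depth_to_cloud(frame), (0.0, 0.0), 0.09, 0.02)
    return cloud, labels


@pytest.fixture(scope="session")
def cap_patch():
    """Jittered-grid sample of a spherical cap: a smooth curved surface
    on which every point has a well-conditioned normal neighborhood."""
    rng = np.random.default_rng(1)
    a, h = 0.03, 0.02
    big_r = (a * a + h * h) / (2 * h)
    g = np.arange(-0.03, 0.0301, 0.0015)
    gx, gy = np.meshgrid(g, g)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    xy = xy + rng.uniform(-3e-4, 3e-4, xy.shape)
    r2 = (xy**2).sum(axis=1)
    keep = r2 < (0.95 * a) ** 2
    z = 0.45 - (np.sqrt(big_r**2 - r2[keep]) - (big_r - h))
    return PointCloud(np.column_stack([xy[keep], z]))


@pytest.fixture(scope="session")
def asym_patch():
    """Wavy surface with off-center bumps: no rotational symmetry, so a
    rigid alignment against it is unique (unlike a spherical cap, which
    ICP can spin freely about its axis)."""
    rng = np.random.default_rng(2)
    g = np.arange(-0.05, 0.0501, 0.002)
    gx, gy = np.meshgrid(g, g)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    xy = xy + rng.uniform(-4e-4, 4e-4, xy.shape)
    x, y = xy[:, 0], xy[:, 1]
    z = (
        0.45
        - 0.006 * np.sin(70 * x) * np.cos(50 * y)
        - 0.030 * np.exp(-((x - 0.015) ** 2 + (y + 0.01) ** 2) / (2 * 0.010**2))
        - 0.022 * np.exp(-((x + 0.02) ** 2 + (y - 0.02) ** 2) / (2 * 0.007**2))
        - 0.018 * np.exp(-((x + 0.01) ** 2 + (y + 0.03) ** 2) / (2 * 0.006**2))
    )
    return PointCloud(np.column_stack([xy, z]))
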