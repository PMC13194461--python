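import numpy as np
import pytest

from seedling3d.cloud import LabeledPointCloud
from seedling3d.synthetic import LayoutConfig, PhenotypeParams, make_seedling, make_tray_scene


@pytest.fixture(scope="session")
def tiny_layout():
    """2x2 tray on a 10 cm plate: fast to generate, same point statistics."""
    return LayoutConfig(trays=1, rows=2, cols=2, pitch=4.1, tray_side=10.0,
                        wall_height=0.5, tray_density=80.0,
                        plant_density=400.0)


@pytest.fixture(scope="session")
def tiny_scene(tiny_layout):
    cloud, truths = make_tray_scene(tiny_layout, t=72.0, seed=7)
    return cloud, truths


@pytest.fixture(scope="session")
def default_scene():
    """One full default tray scene (36 plants, 25 cm tray)."""
    cloud, truths = make_tray_scene(t=72.0, seed=0)
    return cloud, truths


@pytest.fixture(scope="session")
def clean_seedling():
    params = PhenotypeParams(
        height=2.0, stem_diameter=0.10, cotyledon_incl=(30.0, 30.0),
        cotyledon_area=(1.0, 1.0), azimuth=20.0,
    )
    cloud, clean = make_seedling(params, density=400.0, noise_sd=0.0, seed=3)
    return params, cloud, clean


def random_cloud(n=50, seed=0):
    rng = np.random.default_rng(seed)
    sem = rng.integers(0, 3, n)
    inst = np.where(sem == 0, 0, rng.integers(1, 4, n))
    normals = rng.normal(size=(n, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return LabeledPointCloud(
        rng.normal(size=(n, 3)), rng.integers(0, 256, (n, 3)),
        normals, sem, inst,
    )
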