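import numpy as np
import pytest

from pelvimark.geometry import LandmarkSet, PointCloud
from pelvimark.synthetic import ScanRecipe, generate_scan, sample_subject


@pytest.fixture(scope="session")
def canonical_landmarks() -> LandmarkSet:
    """A plausible canonical-pose landmark set (mm)."""
    return LandmarkSet(
        PSIS_L=(-40.0, 0.0, 0.0),
        PSIS_R=(40.0, 0.0, 0.0),
        IC_L=(-120.0, 80.0, 5.0),
        IC_R=(120.0, 80.0, 5.0),
        L1=(0.0, 170.0, 10.0),
        L4=(0.0, 70.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_scan():
    """One deterministic synthetic scan (cloud + landmarks), ~20k points."""
    shape = sample_subject(7)
    recipe = ScanRecipe(shape=shape, n_points=20_000, seed=3)
    return generate_scan(recipe)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_cloud(rng) -> PointCloud:
    return PointCloud(rng.normal(scale=100.0, size=(500, 3)))
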