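import numpy as np
import pytest

from orchardscan import OrchardSpec, PointCloud, generate_orchard


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(-5, 5, (200, 3)))


@pytest.fixture(scope="session")
def small_orchard():
    """Noiseless 2x3 orchard with fixed per-tree geometry."""
    spec = OrchardSpec(
        n_rows=2,
        trees_per_row=3,
        heights=[3.0, 2.8, 3.2, 2.9, 3.1, 2.7],
        crown_d1=[2.3] * 6,
        crown_d2=[2.2] * 6,
        noise_sigma=0.0,
        outlier_fraction=0.0,
        seed=11,
    )
    cloud, truth, labels = generate_orchard(spec)
    return spec, cloud, truth, labels


@pytest.fixture(scope="session")
def noisy_orchard():
    """2x6 orchard with sensor-level noise and sparse outliers."""
    spec = OrchardSpec(
        n_rows=2,
        trees_per_row=6,
        noise_sigma=0.01,
        outlier_fraction=0.01,
        seed=5,
    )
    cloud, truth, labels = generate_orchard(spec)
    return spec, cloud, truth, labels
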