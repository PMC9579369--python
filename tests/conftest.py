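import numpy as np
import pytest

from brainph import (
    CohortSpec,
    GeometricFixture,
    MultichannelRecording,
    generate_cohort_recording,
    generate_fixture,
)


@pytest.fixture
def square_cloud():
    return generate_fixture(GeometricFixture("square"))


@pytest.fixture
def circle20():
    return generate_fixture(GeometricFixture("circle", n_points=20))


@pytest.fixture
def block_cohort_spec():
    """Six blocks of ten channels, strong within-block coupling."""
    partition = [list(range(k * 10, (k + 1) * 10)) for k in range(6)]
    return CohortSpec(
        n_channels=60, n_samples=2000, sampling_rate=250.0,
        block_partition=partition, within_block_r=0.7, between_block_r=0.25,
        seed=11,
    )


@pytest.fixture
def small_recording():
    rng = np.random.default_rng(7)
    return MultichannelRecording(rng.standard_normal((5, 500)), 250.0)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Euclidean distances of a random planar cloud (valid metric)."""
    pts = rng.uniform(size=(n, 2))
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
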