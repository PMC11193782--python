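import numpy as np
import pytest

from melondet.data import generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scenes():
    """A small deterministic batch of synthetic scenes shared across tests."""
    return generate_synthetic_dataset(6, seed=5, size=96, n_fruits=2,
                                      fruit_scale=(0.15, 0.28),
                                      occlusion_rate=0.2)


def random_boxes(rng, n, lo=0.0, hi=100.0, min_size=0.5):
    """Random valid corner-form boxes."""
    xy = rng.uniform(lo, hi - min_size, size=(n, 2))
    wh = rng.uniform(min_size, (hi - lo) / 2, size=(n, 2))
    return np.concatenate([xy, np.minimum(xy + wh, hi)], axis=1)
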