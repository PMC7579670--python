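import numpy as np
import pytest

from drhybrid import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_prob_pairs(rng):
    """1,000 random (grade, probability-vector) pairs."""
    grades = rng.integers(0, 5, size=1000)
    probs = rng.dirichlet(np.ones(5), size=1000)
    return grades, probs


@pytest.fixture(scope="session")
def tiny_image_set():
    """250 uniform-grade synthetic fundus images at size 64 (session-cached)."""
    r = np.random.default_rng(777)
    labels = sd.gen_labels(250, sd.ImbalanceProfile.uniform(), r)
    images = [sd.gen_fundus_image(int(g), 64, r) for g in labels]
    return images, labels
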