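import numpy as np
import pytest

from ventriseg.phantom import PhantomSpec, generate_phantom
from ventriseg.preprocessing import resample_canonical, resample_labels


@pytest.fixture(scope="session")
def phantom_triplet():
    """One deterministic phantom: (native CT, native labels, analytic ml)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def canonical_pair(phantom_triplet):
    """The same phantom standardized: (CanonicalVolume, canonical labels)."""
    native, labels, _ = phantom_triplet
    canonical = resample_canonical(native, source_id="phantom42")
    labels_c = resample_labels(labels, canonical.transform)
    return canonical, labels_c


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(24, 24, 24), n_seeds=3, radius=5):
    """Small random blobby mask for metric oracle tests."""
    grid = np.indices(shape).astype(float)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = rng.uniform(radius, np.array(shape) - radius)
        r = rng.uniform(2, radius)
        d2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
        mask |= d2 <= r ** 2
    return mask
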