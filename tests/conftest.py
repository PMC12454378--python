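import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_patch(rng):
    return rng.random((16, 16))


@pytest.fixture(scope="session")
def small_phantom_features():
    """Features/labels for a small phantom dataset, computed once per session."""
    import brainstage as bs

    ds = bs.make_dataset(12, seed=3, size=96)
    X = bs.HarrisHogExtractor().fit_transform(ds.images)
    return X, np.asarray(ds.labels)
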