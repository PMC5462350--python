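import numpy as np
import pytest

import leafjdsr as lj

# the textbook worked-example pair used across modules
V1 = np.array([1, 0, 0, 1, 0, 0, 1, 1, 0, 0], dtype=np.uint8)
V2 = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0], dtype=np.uint8)


@pytest.fixture(scope="session")
def worked_pair():
    return V1.copy(), V2.copy()


@pytest.fixture(scope="session")
def six_class_data():
    """Medium-separation, low-noise 6-species benchmark, preprocessed once."""
    ds = lj.make_dataset(C=6, per_class=10, separation=0.5, noise="low", seed=42)
    cfg = lj.PreprocessConfig()
    X = np.stack([lj.vectorize(lj.preprocess_image(im, cfg)) for im in ds.images])
    y = np.asarray(ds.labels, dtype=object)
    return ds, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
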