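import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_image():
    """A default positive-class synthetic field, 96 px."""
    from emaclass.simulate import generate_image

    return generate_image("I", size=96, seed=7)


@pytest.fixture
def small_balanced_features():
    """Features + labels for a small balanced synthetic set (12 per class)."""
    from emaclass.classify import LabeledDataset
    from emaclass.features import extract_features
    from emaclass.simulate import DatasetSpec, generate_dataset

    images, labels, _ = generate_dataset(
        DatasetSpec(n_per_class=(12, 12, 12, 12), image_size=64, seed=3)
    )
    X = np.array([extract_features(im) for im in images])
    return LabeledDataset(X, np.array(labels, dtype=object))
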