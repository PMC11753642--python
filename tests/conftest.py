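import numpy as np
import pytest

from mothflame.augmentation import LabeledImage
from mothflame.synthetic import SyntheticFeatureSpec, gen_features


@pytest.fixture(scope="session")
def small_features():
    """3-class, 20/class, 2 informative + 4 noise columns; easy signal."""
    X, y, info = gen_features(
        SyntheticFeatureSpec(n_per_class=20, k_classes=3, d_informative=2,
                             d_noise=4, separation=4.0, seed=11)
    )
    return X, y, info


@pytest.fixture
def tiny_image():
    """2 x 2 single-channel image with distinct pixel values."""
    return LabeledImage(pixels=np.array([[1, 2], [3, 4]], dtype=np.uint8),
                        label="a", origin="tiny")


@pytest.fixture
def rgb_image():
    rng = np.random.default_rng(5)
    return LabeledImage(pixels=rng.integers(0, 256, (8, 8, 3), dtype=np.uint8),
                        label="b", origin="rgb")
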