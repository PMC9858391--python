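import numpy as np
import pytest

from mcwnet import ImageSample, LabeledDataset, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def two_disk_image() -> np.ndarray:
    """Two bright disks on a dark background, noise-free."""
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    img = np.full((64, 64), 0.1)
    img[(yy - 20) ** 2 + (xx - 18) ** 2 <= 8 ** 2] = 0.9
    img[(yy - 44) ** 2 + (xx - 46) ** 2 <= 10 ** 2] = 0.8
    return img


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """Nine tiny synthetic samples, three per class."""
    return generate_dataset(SynthConfig(n_per_class=3, height=64, width=64,
                                        seed=11))


@pytest.fixture
def gray_sample() -> ImageSample:
    rng = np.random.default_rng(5)
    return ImageSample(rng.random((40, 40, 1)).astype(np.float32),
                       label="a", id="a/0")
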