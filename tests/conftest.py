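import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_histogram():
    """Factory for seeded dense random joint histograms."""
    from nlmtdh import Histogram2D

    def make(seed, levels=256):
        g = np.random.default_rng(seed)
        p = g.random((levels, levels))
        p /= p.sum()
        return Histogram2D(p=p, n_pixels=levels * levels)

    return make


@pytest.fixture()
def two_spike_histogram():
    """Mass 0.4 at (50, 50) and 0.6 at (200, 200)."""
    from nlmtdh import Histogram2D

    p = np.zeros((256, 256))
    p[50, 50] = 0.4
    p[200, 200] = 0.6
    return Histogram2D(p=p, n_pixels=100)


@pytest.fixture()
def noisy_two_class_image():
    """64x64 two-class scene, means 60/180, Gaussian noise sigma 10."""
    from nlmtdh import generate_suite

    image, mask, _ = generate_suite("noisy")[0]
    return image, mask
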