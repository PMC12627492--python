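import numpy as np
import pytest

from motiongate import phantom as ph


@pytest.fixture(scope="session")
def spec():
    return ph.default_phantom_spec()


@pytest.fixture(scope="session")
def cam_phantom(spec):
    """Camera-grid phantom: 64 x 64 over the 30 mm body frame."""
    return ph.build_phantom(spec, (64, 64), spec.body_frame_extent_mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_texture(shape, sigma, seed):
    """Band-limited random texture for known-shift tracking constructions."""
    from scipy.ndimage import gaussian_filter

    raw = np.random.default_rng(seed).normal(size=shape)
    tex = gaussian_filter(raw, sigma)
    return (tex - tex.min()) / (tex.max() - tex.min())
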