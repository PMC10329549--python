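import numpy as np
import pytest

from corticad import CorticalMask


def make_rotated_band(theta_deg: float, thickness: float, size: int = 128) -> CorticalMask:
    """Rasterized band of exact perpendicular thickness tilted by theta."""
    theta = np.radians(theta_deg)
    slope = np.tan(theta)
    center = (size - 1) / 2
    cols = np.arange(size)
    rows = np.arange(size)[:, None]
    border = center + slope * (cols - center)
    perp = (rows - border[None, :]) / np.sqrt(1 + slope**2)
    return CorticalMask(((perp >= 0) & (perp < thickness)).astype(np.uint8))


@pytest.fixture
def rotated_band():
    return make_rotated_band


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
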