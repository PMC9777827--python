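import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rasterized_disk(radius_px: int, pad: int = 4) -> np.ndarray:
    """A filled disk of the given radius centred in a square mask."""
    size = 2 * (radius_px + pad) + 1
    c = size // 2
    rr, cc = np.mgrid[0:size, 0:size]
    return (((rr - c) ** 2 + (cc - c) ** 2) <= radius_px ** 2).astype(np.uint8)
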