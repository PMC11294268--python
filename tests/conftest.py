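import numpy as np
import pytest


def random_mask(rng, shape=(32, 32), p=0.3):
    """Random nonempty binary mask."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


def random_blob(rng, shape=(64, 64), radius_range=(5, 20)):
    """Random filled disc — a connected nonempty mask."""
    r = rng.uniform(*radius_range)
    cy = rng.uniform(r, shape[0] - 1 - r)
    cx = rng.uniform(r, shape[1] - 1 - r)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - cy, xx - cx) <= r


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)
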