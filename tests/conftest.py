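import numpy as np
import pytest

from coloseg.containers import LabeledTile
from coloseg.losses import PixelBatch
from coloseg.synthetic import make_tile_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_batch():
    """Seeded 100-pixel, 5-class batch with a few ignored pixels."""
    r = np.random.default_rng(7)
    a = r.normal(size=(100, 5))
    t = r.integers(0, 5, size=100)
    t[:5] = 255
    return PixelBatch.from_activations(a, t)


@pytest.fixture(scope="session")
def tiny_tiles():
    """Twelve 64-px synthetic tiles over 5 well-separated classes."""
    return make_tile_dataset(12, shape=(64, 64), class_set=(0, 2, 5, 8, 13),
                             seed=5)


@pytest.fixture
def checker_tile():
    """Deterministic two-class tile: left half class 0, right half class 5."""
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    img[:, :32] = (150, 100, 180)
    img[:, 32:] = (250, 160, 185)
    mask = np.zeros((64, 64), dtype=np.int64)
    mask[:, 32:] = 5
    return LabeledTile(image=img, mask=mask, spacing_um=1.0)


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def relative_error(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if max(na, nb) == 0:
        return 0.0
    return float(np.linalg.norm(a - b) / max(na, nb))
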