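import numpy as np
import pytest

from voxelflow import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def scalar_volume(arr: np.ndarray) -> Volume:
    """Wrap a (z,y,x)-ordered float array as a 1-channel f32 Volume."""
    arr = np.asarray(arr, dtype=np.float32)
    dims = tuple(arr.shape[::-1])
    return Volume(dims, 1, "f32", arr[..., None].copy())


def random_volume(rng, dims) -> Volume:
    return scalar_volume(rng.random(tuple(dims)[::-1]).astype(np.float32))


@pytest.fixture
def make_scalar_volume():
    return scalar_volume


@pytest.fixture
def make_random_volume():
    return random_volume
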