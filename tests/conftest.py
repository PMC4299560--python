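import numpy as np
import pytest

from ctild.phantom import PhantomSpec, generate_phantom
from ctild.volume import CTVolume, LungMask


@pytest.fixture
def small_phantom_spec():
    return PhantomSpec(grid_shape=(8, 64, 64), target_fibrotic_fraction=0.3, seed=11)


@pytest.fixture
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


def make_volume(values, spacing=(7.0, 0.7, 0.7)) -> CTVolume:
    return CTVolume.from_hu(np.asarray(values), spacing)


def uniform_volume(hu: int, shape=(4, 16, 16)) -> CTVolume:
    return make_volume(np.full(shape, hu, dtype=np.int16))


def full_mask(volume: CTVolume) -> LungMask:
    return LungMask(mask=np.ones(volume.shape, dtype=bool))
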