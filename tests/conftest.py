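import numpy as np
import pytest

from distsynth.datagen import CenterSpec, PhantomSpec, make_center_data


@pytest.fixture()
def phantom():
    return PhantomSpec(image_size=16, n_classes=2,
                       intensity_table=((0.1,), (0.45,), (0.8,)),
                       noise_sd=0.03)


@pytest.fixture()
def center():
    return CenterSpec("A", 8, (0,), seed=11)


@pytest.fixture()
def center_data(phantom, center):
    return make_center_data(center, phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
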