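import numpy as np
import pytest

from faseg import ModelConfig, PhantomSpec, build_model, generate_sample
from faseg.imaging import LUNG_WINDOW, apply_window


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(ModelConfig.preset_tiny(), seed=7)


@pytest.fixture(scope="session")
def phantom_batch():
    """8 windowed 64x64 phantoms with lesions, plus their masks."""
    spec = PhantomSpec(n_samples=8, side=64, lesion_probability=1.0, seed=7)
    imgs, masks = [], []
    for i in range(8):
        ct, mk = generate_sample(spec, i)
        imgs.append(apply_window(ct, LUNG_WINDOW))
        masks.append(mk.pixels)
    return np.stack(imgs), np.stack(masks)
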