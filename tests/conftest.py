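import numpy as np
import pytest

from fcmbias import FCMBiasCorrector, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The standard evaluation phantom (128x128, 3 classes, seed 17)."""
    return generate_phantom()


@pytest.fixture(scope="session")
def default_fit(default_phantom):
    """Default-parameter correction of the standard phantom."""
    return FCMBiasCorrector(n_classes=3).fit(default_phantom.image)


@pytest.fixture(scope="session")
def clean_two_class_phantom():
    """Bias-free, noise-free two-level stripes phantom."""
    return generate_phantom(PhantomSpec(
        shape=(64, 64), class_means=(0.2, 0.8), layout="stripes",
        bias_amplitude=0.0, noise_sigma=0.0, background_margin=4, seed=3,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
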