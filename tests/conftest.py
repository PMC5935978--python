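import numpy as np
import pytest

from nodulequant import NoduleSpec, simulate_nodule


@pytest.fixture(scope="session")
def sharp_spec():
    """Blur-free phantom with well-separated component HU distributions."""
    return NoduleSpec(
        diameter_cm=1.5,
        lepidic_fraction=0.5,
        blur_sigma_mm=0.0,
        hu_ggo_sd=30.0,
        hu_solid_sd=30.0,
        hu_lung_sd=30.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def sharp_phantom(sharp_spec):
    return simulate_nodule(sharp_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
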