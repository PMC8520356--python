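from dataclasses import replace

import numpy as np
import pytest

from neoventry import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom with no noise, bias or blur: exact gray levels."""
    spec = replace(
        PhantomSpec(), noise_sigma=0.0, bias_amplitude=0.0, psf_sigma=0.0
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantoms():
    """100 seeded phantoms at moderate noise, reused across invariance tests."""
    return [
        make_phantom(replace(PhantomSpec(), noise_sigma=8.0, seed=s))
        for s in range(100)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
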