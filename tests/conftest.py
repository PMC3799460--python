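import numpy as np
import pytest
from hypothesis import settings

from nanostain import SimConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def config():
    """Small, fast simulation condition used across the unit tests."""
    return SimConfig(
        native_extension_um=8.0,
        frames_per_molecule=8,
        extension_fluct_sd_um=0.2,
        center_diffusion_step_um=0.05,
    )


@pytest.fixture
def quiet_config():
    """Noise-free, frozen-molecule variant for exactness tests."""
    return SimConfig(
        native_extension_um=8.0,
        frames_per_molecule=4,
        extension_fluct_sd_um=0.0,
        center_diffusion_step_um=0.0,
        molecule_extension_sd_um=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1)
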