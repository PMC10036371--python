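import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mmntrack import (  # noqa: E402
    NoiseModel,
    ParadigmConfig,
    build_templates,
    generate_sequence,
    simulate_block,
    synthesize_epochs,
)


@pytest.fixture(scope="session")
def small_config():
    """A short block (300 tones) that keeps unit tests fast: counts are
    round(300 * p) = 18 per deviant, 246 standards."""
    return ParadigmConfig(n_tones=300, seed=7)


@pytest.fixture(scope="session")
def default_config():
    return ParadigmConfig()


@pytest.fixture(scope="session")
def templates(small_config):
    return build_templates(small_config)


@pytest.fixture(scope="session")
def noiseless_epochs(small_config, templates):
    """Noise-free block: every epoch equals its condition template."""
    noise = NoiseModel(
        white_sd_uV=0.0, pink_sd_uV=0.0, trial_amplitude_jitter=0.0, seed=1
    )
    seq = generate_sequence(small_config)
    return synthesize_epochs(seq, templates, noise, small_config)


@pytest.fixture(scope="session")
def noisy_epochs(small_config):
    return simulate_block(small_config, NoiseModel(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230310)
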