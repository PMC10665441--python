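import numpy as np
import pytest

from dynica import ExperimentDesign, SyntheticConfig, generate_truth


@pytest.fixture(scope="session")
def design6():
    """Six-metal default design (36 induction / 120 recovery columns)."""
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_config():
    """Small noiseless study: 60 promoters, one component per metal."""
    return SyntheticConfig(
        n_promoters=60,
        n_components=6,
        weight_sparsity=0.1,
        noise_sd=0.0,
        measurement_sd=0.0,
        spike_prob=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config, design6):
    return generate_truth(small_config, design6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
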