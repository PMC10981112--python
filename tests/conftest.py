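import numpy as np
import pytest

from scarres import phantom


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic cohort shared across tests."""
    cfg = phantom.PhantomConfig(
        n_volumes=6, slices_per_volume=(6, 8), seed=11
    )
    return phantom.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_config():
    return phantom.PhantomConfig(
        n_volumes=3, slices_per_volume=(4, 5), noise_sd=0.0, seed=21
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return phantom.generate_cohort(noise_free_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
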