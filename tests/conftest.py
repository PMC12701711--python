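import numpy as np
import pytest

from artifactlab.phantom import PhantomSpec, generate_phase_series
from artifactlab.preprocess import truncate_and_normalize


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        grid_shape=(32, 32, 48), n_phases=2, noise_sd=20.0,
        diaphragm_amplitude=6.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_series(small_spec):
    return generate_phase_series(small_spec)


@pytest.fixture(scope="session")
def norm_t00(small_series):
    return truncate_and_normalize(small_series.volume("T00"))


@pytest.fixture(scope="session")
def norm_t50(small_series):
    return truncate_and_normalize(small_series.volume("T50"))


@pytest.fixture(scope="session")
def lung_t00(small_series):
    return small_series.lung_mask("T00")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
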