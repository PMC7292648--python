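import numpy as np
import pytest

from remyelin.config import VolumeSpec, default_cohort


@pytest.fixture(scope="session")
def volume():
    return VolumeSpec()


@pytest.fixture(scope="session")
def noisefree_control(volume):
    """Control cohort without drift or jitter: downstream stages must
    recover ground truth exactly."""
    from remyelin.synthetic import generate_cell_population
    cfg = default_cohort("control", n_mice=2, drift_sd=0.0, jitter_sd=0.0)
    obs, truth = generate_cell_population(volume, cfg, seed=11)
    return obs, truth, cfg


@pytest.fixture(scope="session")
def cuprizone_cohort(volume):
    """Default-condition cuprizone cohort with drift and jitter."""
    from remyelin.synthetic import generate_cell_population
    cfg = default_cohort("cuprizone")
    obs, truth = generate_cell_population(volume, cfg, seed=7)
    return obs, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
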