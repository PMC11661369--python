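import numpy as np
import pytest

from phantomforge.mixing import LinearMixingModel
from phantomforge.synth import published_model
from phantomforge.wmc import MediumModel, build_lut, simulate_white_mc


@pytest.fixture(scope="session")
def model() -> LinearMixingModel:
    """Mixing model with the reported coefficients."""
    return published_model()


@pytest.fixture(scope="session")
def wmc_run_big():
    """Reference white-MC run (1e6 photons, tissue-like n and g).

    Session-scoped: this is the expensive fixture shared by the transport
    tests, the SFDI pipeline tests and the acceptance criteria.
    """
    medium = MediumModel(n=1.4, g=0.9, mus_ref=10.0)
    return simulate_white_mc(medium, 1_000_000, seed=20260906, max_path=200.0)


@pytest.fixture(scope="session")
def lut_big(wmc_run_big):
    return build_lut(wmc_run_big)


@pytest.fixture(scope="session")
def wmc_run_small():
    """Cheap run for determinism / monotonicity checks."""
    medium = MediumModel(n=1.4, g=0.9, mus_ref=10.0)
    return simulate_white_mc(medium, 20_000, seed=11, max_path=100.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
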