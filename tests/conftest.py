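import numpy as np
import pytest

from tgnet.synthetic import make_scenario, sample_panel


@pytest.fixture(scope="session")
def small_scenario():
    """Tiny two-phase scenario for fitter tests (p=3, M=2, n=50)."""
    return make_scenario(p=3, M=2, n_phases=2, edges_per_phase=2, effect=0.5, seed=3, n_per_period=50)


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    return sample_panel(small_scenario, burn=200, thin=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
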