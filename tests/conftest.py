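import pytest
from hypothesis import settings

from acylscreen import library, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.SimConfig(seed=7, n_amines=12, n_fas=6, spike_n=5, decoy_n=30)


@pytest.fixture(scope="session")
def small_library(small_cfg):
    amines, fas = synthetic.gen_compound_lists(small_cfg)
    return library.build_library(amines, fas)


@pytest.fixture(scope="session")
def full_library():
    """The full combinatorial screen scale: 460 amines x 53 fatty acids."""
    cfg = synthetic.SimConfig(seed=0)
    amines, fas = synthetic.gen_compound_lists(cfg)
    return library.build_library(amines, fas)
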