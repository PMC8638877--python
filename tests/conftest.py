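import numpy as np
import pytest

from ecitt import BlockConfig, Counterbalance, ECITT_S1


@pytest.fixture
def cb():
    return Counterbalance("P001", "top")


@pytest.fixture
def default_cfg():
    return BlockConfig.ecitt()


@pytest.fixture
def mini_cfg():
    # small enough to enumerate exhaustively: 6 trials, 2 inhibitory,
    # 2-trial lead-in, run caps 3 prepotent / 1 inhibitory
    return BlockConfig(n_trials=6, n_inhibitory=2, lead_in=2,
                       max_run_prepotent=3, max_run_inhibitory=1)


@pytest.fixture
def toddler_variant():
    return ECITT_S1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
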