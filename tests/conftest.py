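import numpy as np
import pytest

from rovingsj.core import ObserverParams, SingleTrial
from rovingsj.adaptive import make_design
from rovingsj.simulate import SyntheticObserver, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(20160324)


@pytest.fixture(scope="session")
def dual_block_constant_bias():
    """One Exp-1b-sized dual-presentation block from a constant-bias
    observer (PSS 0, sigma 50 ms, c = 30 ms)."""
    rng = np.random.default_rng(11)
    obs = SyntheticObserver(params=ObserverParams(
        mu=0.0, sigma=50.0, bias_form="constant", bias=30.0))
    return simulate_session(obs, make_design("exp1b_2xsj"), rng)


@pytest.fixture(scope="session")
def toj_block():
    """One Exp-1b TOJ block (100 trials) from an unbiased observer."""
    rng = np.random.default_rng(12)
    obs = SyntheticObserver(params=ObserverParams(mu=-10.0, sigma=60.0))
    return simulate_session(obs, make_design("exp1b_toj"), rng)


@pytest.fixture(scope="session")
def sj_dataset():
    """Constant-stimuli SJ dataset from a symmetric-criteria observer."""
    rng = np.random.default_rng(13)
    obs = SyntheticObserver(params=ObserverParams(
        mu=0.0, sigma=40.0, crit_low=-60.0, crit_high=80.0))
    soas = np.tile([-300, -200, -120, -80, -40, 0, 40, 80, 120, 200, 300], 18)
    from rovingsj.simulate import simulate_response
    return [SingleTrial(float(s), simulate_response(obs, "sj", float(s), rng))
            for s in soas]
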