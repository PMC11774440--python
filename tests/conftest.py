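import numpy as np
import pytest

from taskgates import (Curriculum, forgetful_baseline, init_state, integrate,
                       make_teachers)


@pytest.fixture(scope="session")
def teachers_2x8():
    """Two orthogonal teachers with 8 unit-norm rows in 32 input dims."""
    return make_teachers(2, 32, 8, seed=0)


@pytest.fixture(scope="session")
def flexible_run(teachers_2x8):
    """One flexible two-task run under the studied timescales
    (tau_c=0.03, tau_w=1.3, unit blocks), shared across metric tests."""
    state = init_state(2, 32, 8, seed=0)
    curr = Curriculum(block_length=1.0, n_blocks=24, seed=0)
    return integrate(state, teachers_2x8, curr)


@pytest.fixture(scope="session")
def forgetful_run(teachers_2x8):
    """The matched forgetful control of ``flexible_run``."""
    state = forgetful_baseline(init_state(2, 32, 8, seed=0))
    curr = Curriculum(block_length=1.0, n_blocks=24, seed=0)
    return integrate(state, teachers_2x8, curr)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
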