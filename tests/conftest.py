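import numpy as np
import pytest

from statedyn import synth


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small generated cohort shared by read-only tests."""
    cfg = synth.SimulationConfig(n_subjects=4, n_timepoints=160, n_trials=48,
                                 seed=7)
    return synth.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
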