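import numpy as np
import pytest

from fomopipe.simulate import SimConfig, gen_keypoints, gen_schedule


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Short session: 6 trials, 10-s habituation, otherwise study defaults."""
    return SimConfig(seed=1, n_trials=6, habituation_s=10.0)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    sched = gen_schedule(small_cfg)
    track, truth = gen_keypoints(small_cfg, sched)
    return small_cfg, sched, track, truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
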