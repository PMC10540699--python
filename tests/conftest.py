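import numpy as np
import pytest

from duplescales import synth
from duplescales.montage import channel_adjacency, positions_2d
from duplescales.paradigm import build_schedule


@pytest.fixture(scope="session")
def pos2d():
    return positions_2d()


@pytest.fixture(scope="session")
def adjacency(pos2d):
    return channel_adjacency(pos2d)


@pytest.fixture(scope="session")
def schedule_full():
    """The full 240-trial, 12-block experiment plan."""
    return build_schedule(20240)


@pytest.fixture(scope="session")
def schedule_small():
    """Scaled-down plan: 3 blocks x 4 trials (one block per condition)."""
    return build_schedule(11, n_blocks=3, trials_per_block=4)


@pytest.fixture(scope="session")
def schedule_mid():
    """6 blocks x 6 trials: 12 trials (and deviants) per condition."""
    return build_schedule(42, n_blocks=6, trials_per_block=6)


@pytest.fixture(scope="session")
def epochs_mid(schedule_mid):
    return synth.synth_epochs(schedule_mid, synth.SynthEEGParams(), seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
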