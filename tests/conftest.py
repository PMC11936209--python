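import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from beatbench.simulate import get_preset, synth_beatset


@pytest.fixture(scope="session")
def normal_params():
    return get_preset("normal_v1")


@pytest.fixture(scope="session")
def lbbb_params():
    return get_preset("lbbb_v1")


@pytest.fixture(scope="session")
def normal_beats_50(normal_params):
    return synth_beatset(normal_params, 50, seed=101)


@pytest.fixture(scope="session")
def normal_beats_500(normal_params):
    return synth_beatset(normal_params, 500, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
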