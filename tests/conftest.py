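import numpy as np
import pytest

from numecog.stim import StimParams, build_sequential_plan


@pytest.fixture(scope="session")
def sequential_plan():
    return build_sequential_plan(StimParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
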