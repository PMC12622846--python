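import numpy as np
import pytest
from hypothesis import settings

import twindom as td

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_cfg():
    """Small but fully featured run: moderate promoter, steady-state activities."""
    return td.make_config(n_steps=5_000, burn_in_steps=500, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
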