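import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_small_spec, small_config, toy_epochs  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec_factory():
    return make_small_spec


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture
def toy_epochs_factory():
    return toy_epochs
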