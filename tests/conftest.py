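import logging

import numpy as np
import pytest

from attnflow.containers import build_block_design
from attnflow.dcm import HemoParams
from attnflow.model_space import enumerate_feedback_models
from attnflow.synthetic import default_neural_truth, standard_design

logging.getLogger("attnflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_design():
    """The standard acquisition: 8x16 s blocks, 8x12 s blanks, TR 2 s."""
    return standard_design()


@pytest.fixture(scope="session")
def fast_design():
    """Same block structure at coarser integration resolution (for speed)."""
    return standard_design(microtime_bins=8)


@pytest.fixture(scope="session")
def feedback_space():
    return enumerate_feedback_models()


@pytest.fixture(scope="session")
def gen_spec(feedback_space):
    """The generating structure: modulation on the IFJ -> visual feedback."""
    return feedback_space.spec("3")


@pytest.fixture(scope="session")
def truth_params(gen_spec):
    return default_neural_truth(gen_spec)


@pytest.fixture(scope="session")
def hemo():
    return HemoParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
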