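import numpy as np
import pytest

from gen3d import synthetic
from gen3d.optimize import OptimizerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_truth():
    """30-locus synthetic ground truth with binary contacts, no noise."""
    return synthetic.generate(30, seed=100)


@pytest.fixture
def tiny_cfg():
    """A configuration small enough for sub-second full-pipeline runs."""
    return OptimizerConfig(
        adapt_iters=60,
        adapt_trials=5,
        sa_iters=3,
        ga_mutations=50,
        ensemble_max=8,
        seed=7,
    )
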