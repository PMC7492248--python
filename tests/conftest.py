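import pytest

from leaflex import (
    NoiseModel,
    make_ground_truth,
    table1_experiments,
)


@pytest.fixture(scope="session")
def truth():
    """Default RBC-like asymmetric ground truth."""
    return make_ground_truth(seed=1)


@pytest.fixture(scope="session")
def experiments(truth):
    """The three optimized exchange conditions (bSM / POPC / POPS)."""
    return table1_experiments(truth)


@pytest.fixture()
def noiseless():
    return NoiseModel(cv=0.0, detection_limit=0.0, seed=0)
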