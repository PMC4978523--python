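import numpy as np
import pytest

from numadapt import ExperimentDesign, ObserverParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_observer():
    """Observer with unit gains and no noise: responses equal true numerosity."""
    return ObserverParams.from_gains(1.0, 1.0, 1.0, 1.0, weber_fraction=0.0)


@pytest.fixture
def biased_observer():
    """Noise-free observer with the 20%-effect gain pair at the adapted side."""
    return ObserverParams.from_gains(0.9, 1.1, 1.0, 1.0, weber_fraction=0.0)


@pytest.fixture
def small_design():
    return ExperimentDesign(subjects=2, trials_per_cell=2, seed=7)
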