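import numpy as np
import pytest

from cleftscope.synthetic import (
    KineticSpec,
    ToyStructureSpec,
    TrajectorySpec,
    make_breathing_trajectory,
    make_kinetic_dataset,
    make_toy_structure,
)


@pytest.fixture(scope="session")
def toy():
    """Default toy structure with its ground-truth manifest."""
    return make_toy_structure(ToyStructureSpec(seed=0))


@pytest.fixture(scope="session")
def breathing():
    """Default 100-frame open/closed breathing trajectory with manifest."""
    return make_breathing_trajectory(TrajectorySpec(seed=0))


@pytest.fixture(scope="session")
def noisy_kinetics():
    """50 replicate rate datasets at 5% relative noise (seed 11)."""
    spec = KineticSpec(noise_sd=0.05, n_replicates=50, seed=11)
    return make_kinetic_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
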