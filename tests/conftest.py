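import numpy as np
import pytest

from disgaze.synthetic_data import (
    GazeSimConfig,
    RLSimConfig,
    make_design,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """Eight-participant study with the default injected avoidance effect and
    a positive drug x phase x stimulus interaction, fixations included."""
    design = make_design(8, seed=11)
    return simulate_study(
        design,
        GazeSimConfig(seed=11, drug_phase_interaction=0.7),
        RLSimConfig(seed=11),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
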