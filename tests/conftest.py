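import numpy as np
import pytest

from seqvpc import (NBFeatureParams, ParameterConfig, SimulationTruth,
                    draw_feature_parameters, make_design, simulate_dataset)


@pytest.fixture(scope="session")
def small_nb_dataset():
    """A 40-feature NB dataset on 20 strains x 3 replicates, with truth."""
    rng = np.random.default_rng(1234)
    design = make_design(20, 3)
    params = draw_feature_parameters(ParameterConfig(), 40, rng, model="nb")
    truth = SimulationTruth(params, design, "nb")
    cm = simulate_dataset(truth, rng)
    return cm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
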