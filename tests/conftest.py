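import numpy as np
import pytest

import steadynet as sn


@pytest.fixture()
def toy_glv():
    """2-taxon GLV community with known equilibria.

    A = [[-1, 0.5], [-0.5, -1]], r = (1, 1): steady states are
    x^{1} = (1, 0), x^{2} = (0, 1), x^{1,2} = (1.2, 0.4).
    """
    net = sn.EcologicalNetwork(
        adjacency=np.array([[-1.0, 0.5], [-0.5, -1.0]]), connectivity=1.0
    )
    return sn.DynamicsModel(kind="glv", network=net, growth_rates=np.array([1.0, 1.0]))


@pytest.fixture()
def toy_samples(toy_glv):
    rows = [
        sn.glv_steady_state(toy_glv, {0}),
        sn.glv_steady_state(toy_glv, {0, 1}),
    ]
    return sn.SampleSet(abundances=np.array(rows))


@pytest.fixture()
def glv8():
    """Noiseless 8-taxon GLV community with enough samples for inference."""
    rng = np.random.default_rng(11)
    model = sn.random_glv_model(8, 0.4, rng=rng)
    samples, _ = sn.generate_sample_set(model, 48, rng=rng)
    return model, samples
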