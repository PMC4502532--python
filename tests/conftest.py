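import numpy as np
import pytest

import scorepgg as sp


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def params_fig1():
    """The baseline game of the worked examples: s=5, n=1500, r=4."""
    return sp.validate_params(n=1500, s=5, r=4.0, p=1.0)


@pytest.fixture
def small_params():
    return sp.validate_params(n=20, s=5, r=4.0, p=0.5)


def random_state(params, rng, coop_fraction=0.5, score_fraction=0.5):
    """A valid random PopulationState for property tests."""
    n = params.n
    strategies = (rng.random(n) < coop_fraction).astype(np.int64)
    scores = (rng.random(n) < score_fraction).astype(np.int64)
    groups = sp.match_by_score(scores, params, rng)
    return sp.PopulationState(strategies, scores, groups)
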