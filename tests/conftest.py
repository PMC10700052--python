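import numpy as np
import pytest

import effsel as es


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def markov_trajectory():
    """A 200-generation trajectory under the default switching regime."""
    cfg = es.SimConfig(ne=1000, regime=es.default_markov_regime(),
                       init_freq=0.5, max_generations=200, seed=7)
    return es.simulate(cfg)


@pytest.fixture(scope="session")
def paradox_trajectory():
    """A conditioned frequency-dependent run: fixed despite f_G < 1.

    Fitness 1.01 below frequency 0.99, else 0.9 (Ne=1000, single-copy start).
    The seed was selected so the run realizes the conditioned scenario of
    interest — fixation with geometric mean fitness below 1 — mirroring the
    worked single-trajectory example.
    """
    regime = es.FrequencyDependentFitness(f_low=1.01, f_high=0.9, threshold=0.99)
    cfg = es.SimConfig(ne=1000, regime=regime, init_copies=1,
                       max_generations=100_000, seed=208)
    traj = es.simulate(cfg)
    assert traj.outcome == "fixed"
    return traj
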