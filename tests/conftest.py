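import numpy as np
import pytest

from succdyn import (
    CalibratedParams,
    FixedParams,
    experiment_configs,
    simulate,
)


@pytest.fixture(scope="session")
def fixed():
    return FixedParams()


@pytest.fixture(scope="session")
def params():
    return CalibratedParams()


@pytest.fixture(scope="session")
def configs():
    return experiment_configs()


@pytest.fixture(scope="session")
def g1_trajectory(params, fixed, configs):
    """The calibrated G1 batch run, shared across tests."""
    return simulate(configs["G1"], params, fixed)


def random_admissible_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random states spanning the physically plausible ranges of a batch."""
    states = np.empty((n, 10))
    states[:, 0] = rng.uniform(0.0, 0.5, n)        # G, mol/L
    states[:, 1] = rng.uniform(0.0, 8e-5, n)       # G3P, mol/molX
    states[:, 2] = rng.uniform(0.0, 8e-5, n)       # PEP
    states[:, 3] = rng.uniform(0.0, 1.5e-4, n)     # P
    states[:, 4] = rng.uniform(2e-4, 1e-1, n)      # X, molX/L
    states[:, 5] = rng.uniform(0.0, 0.3, n)        # SA, mol/L
    states[:, 6] = rng.uniform(0.0, 0.12, n)       # AA
    states[:, 7] = rng.uniform(0.0, 0.08, n)       # FA
    ratio = rng.uniform(0.0, 1.0, n)               # energy charge per gX
    total = states[:, 4] * 24.55 * rng.uniform(0.5, 1.5, n)
    states[:, 8] = ratio * total                   # ATP
    states[:, 9] = (1 - ratio) * total             # ADP
    return states
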