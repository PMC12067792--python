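import warnings

import numpy as np
import pytest

import cdmhier as ch


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    """Boundary fits legitimately emit RuntimeWarnings (empty groups); keep
    the test log readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def linear3():
    return ch.hierarchy_preset("linear", 3)


@pytest.fixture(scope="session")
def sim_k3(linear3):
    """One simulated null-regime dataset: K=3, linear hierarchy, high-quality
    items, N=300."""
    root = np.random.SeedSequence(2024)
    q_rng, a_rng = (np.random.default_rng(s) for s in root.spawn(2))
    Q = ch.gen_qmatrix(30, 3, q_rng)
    params = ch.gen_item_params(Q, "high")
    positions = ch.gen_attributes(300, linear3, "uniform", a_rng)
    X = ch.gen_responses(positions, Q, params, a_rng)
    return {"X": X, "Q": Q, "positions": positions, "params": params}


@pytest.fixture(scope="session")
def sat_fit_k3(sim_k3):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ch.fit(sim_k3["X"], sim_k3["Q"])


def small_interior_instance(seed=11, N=80, J=6, K=2):
    """A small dataset with no hierarchy: every class populated, parameters
    interior — convenient for derivative oracles."""
    rng = np.random.default_rng(seed)
    Q = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]])[:J]
    params = ch.gen_item_params(Q, "moderate")
    positions = rng.integers(0, 2 ** K, size=N)
    X = ch.gen_responses(positions, Q, params, rng)
    return X, Q
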