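import numpy as np
import pytest

import scarnet as sn


@pytest.fixture(scope="session")
def default_params():
    return sn.ParameterSet()


@pytest.fixture(scope="session")
def mesh61():
    return sn.Mesh.uniform(61, 10.0)


@pytest.fixture(scope="session")
def wounded_result(default_params, mesh61):
    """One full 365-day wounded run at desk resolution."""
    return sn.simulate(default_params, mesh61, sn.SolverConfig())


@pytest.fixture(scope="session")
def tiny_corpus():
    """50-row smoke corpus at coarse resolution (fixed seed)."""
    return sn.generate_corpus(50, master_seed=42, n_nodes=61)


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    return sn.split_and_scale(tiny_corpus, n_folds=5, seed=42)


def make_uniform_state(params, n=21, length=10.0, **fields):
    """Homogeneous state helper with optional per-species overrides."""
    x = np.linspace(0.0, length, n)
    state = sn.equilibrium_state(params, x)
    for name, value in fields.items():
        setattr(state, name, np.full(n, float(value)))
    return state
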