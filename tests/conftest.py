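import numpy as np
import pytest

from resdenoise.egnn import EGNNConfig, EGNNParams
from resdenoise.fixtures import FixtureSpec, make_corpus, make_helix_structure
from resdenoise.graph import GraphConfig, build_residue_graph
from resdenoise.seq_encode import EmbeddingProvider


@pytest.fixture(scope="session")
def helix30():
    return make_helix_structure(30, seed=1)


@pytest.fixture(scope="session")
def helix50():
    return make_helix_structure(50, seed=2)


@pytest.fixture(scope="session")
def tiny_corpus():
    return make_corpus(FixtureSpec(n_proteins=3, length_range=(20, 30), seed=7))


@pytest.fixture(scope="session")
def provider():
    return EmbeddingProvider(mode="one_hot")


@pytest.fixture
def small_graph(helix30, provider):
    g = build_residue_graph(helix30, GraphConfig(k=10))
    g.W_V = provider.encode(helix30.sequence)
    return g


@pytest.fixture
def small_egnn():
    config = EGNNConfig(layers=6, hidden=16, input_dim=33, message_dim=16)
    return config, EGNNParams(config, seed=3)


def rigid_motion(seed=0):
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, size=3)
    return R, t


def transform_structure(structure, R, t):
    """Apply a rigid motion to every backbone atom (returns a deep copy)."""
    import copy

    out = copy.deepcopy(structure)
    for r in out.residues:
        for name in ("N", "CA", "C", "O", "CB"):
            setattr(r, name, getattr(r, name) @ R.T + t)
    return out
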