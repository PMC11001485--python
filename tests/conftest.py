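import numpy as np
import pytest

from molemcl import (
    EncoderConfig,
    FeatureVocab,
    generate_fixture_molecules,
    init_params,
    smiles_to_graph,
)


@pytest.fixture(scope="session")
def vocab():
    return FeatureVocab()


@pytest.fixture(scope="session")
def tiny_config():
    """A 2-layer, 8-dimensional encoder for fast numerical checks."""
    return EncoderConfig(num_layers=2, hidden_dim=8, projection_hidden_dim=8, projection_out_dim=8)


@pytest.fixture(scope="session")
def tiny_params(tiny_config, vocab):
    return init_params(tiny_config, vocab, seed=0)


@pytest.fixture(scope="session")
def fixture_smiles():
    return generate_fixture_molecules(64, seed=0)


@pytest.fixture(scope="session")
def fixture_graphs(fixture_smiles, vocab):
    return [smiles_to_graph(s, vocab) for s in fixture_smiles]


def brute_force_nt_xent(anchors: np.ndarray, partners: np.ndarray, tau: float) -> float:
    """Independent double-loop NT-Xent oracle (explicit cosines and exps)."""
    import math

    def cos(u, v):
        nu, nv = math.sqrt(sum(x * x for x in u)), math.sqrt(sum(x * x for x in v))
        if nu == 0 or nv == 0:
            return 0.0
        return sum(a * b for a, b in zip(u, v)) / (nu * nv)

    B = len(anchors)
    losses = []
    for i in range(B):
        num = math.exp(cos(anchors[i], partners[i]) / tau)
        den = sum(math.exp(cos(anchors[i], partners[j]) / tau) for j in range(B) if j != i)
        losses.append(-math.log(num / den))
    return sum(losses) / B
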