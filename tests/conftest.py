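import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tregmark.coregnet import CoregNetwork
from tregmark.diffexp import ExpressionMatrix
from tregmark.synth import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A scaled-down study: quick to simulate, same structure as the default."""
    return SimConfig(
        n_genes=300,
        n_planted_markers=8,
        module_spec=[(None, 10, 0.9), (None, 10, 0.9)],
        cells_per_population=60,
        cohort_n=60,
        seed=11,
    )


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """3 genes x 6 log-scale samples in two populations (test: A, reference: B)."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 5.0, 2.0],
            "a2": [2.0, 5.5, 2.0],
            "a3": [3.0, 4.5, 2.0],
            "b1": [4.0, 5.0, 2.0],
            "b2": [5.0, 5.5, 2.0],
            "b3": [6.0, 4.5, 2.0],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {"population": ["A"] * 3 + ["B"] * 3},
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values, meta, scale="log-intensity")


def make_network(edges, nodes=(), m_samples=9) -> CoregNetwork:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, r=0.9, p=0.001)
    return CoregNetwork(g, m_samples=m_samples)


@pytest.fixture
def triangle_net() -> CoregNetwork:
    """Triangle a-b-c plus isolated nodes d, e (the exhaustive-null fixture)."""
    return make_network([("a", "b"), ("b", "c"), ("a", "c")], nodes=["d", "e"])


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
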