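import itertools

import networkx as nx
import numpy as np
import pytest

from ehrnet import BlockSpec, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two correlated blocks + noise + redundant columns, mild missingness."""
    blocks = (BlockSpec("cardio", 6, 6.0, 0.3), BlockSpec("lipid", 6, 6.0, 0.25))
    betas = {f"cardio_{i + 1}": 0.6 for i in range(6)}
    betas.update({f"lipid_{i + 1}": 0.6 for i in range(6)})
    spec = CohortSpec(
        n_patients=1200,
        blocks=blocks,
        n_noise_features=20,
        outcome_coefficients=betas,
        outcome_intercept=-2.5,
        n_redundant=2,
        missing_rate=0.01,
        seed=11,
    )
    table, truth = generate_cohort(spec)
    return spec, table, truth


@pytest.fixture
def two_triangles():
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return G


@pytest.fixture
def two_cliques_bridge():
    G = nx.Graph()
    for block in ([0, 1, 2, 3], [4, 5, 6, 7]):
        G.add_edges_from(itertools.combinations(block, 2))
    G.add_edge(3, 4)
    return G


@pytest.fixture
def triangle_ring():
    G = nx.Graph()
    triangles = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
    for tri in triangles:
        G.add_edges_from(itertools.combinations(tri, 2))
    G.add_edges_from([(2, 3), (5, 6), (8, 0)])
    return G


@pytest.fixture
def rng():
    return np.random.default_rng(123)
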