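import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coreactnet as cn


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    """Three animals x two regions of hand-checkable counts."""
    rows = [
        ("a1", "CFC", "BLA", 200, 10, 20, 2),
        ("a1", "CFC", "PL", 100, 100, 100, 100),
        ("a2", "CFC", "BLA", 1000, 50, 80, 10),
        ("a2", "CFC", "PL", 500, 40, 30, 6),
        ("a3", "HC", "BLA", 800, 16, 24, 1),
        ("a3", "HC", "PL", 400, 20, 12, 1),
    ]
    return pd.DataFrame(rows, columns=cn.io.COUNT_COLUMNS)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset shared across tests."""
    counts, metadata, truth = cn.preset_study_like(seed=11)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def study_react(study_dataset):
    counts, _, _ = study_dataset
    return cn.reactivation_table(counts)


def random_weighted_graph(rng, n_max=6, p_edge=0.7, ensure_edge=True) -> nx.Graph:
    """Random positive-weight graph used against the brute-force oracles."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph(sign_mode="positive", group="random")
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w = float(rng.uniform(0.1, 1.0))
                g.add_edge(i, j, weight=w, r=w)
    if ensure_edge and g.number_of_edges() == 0:
        g.add_edge(0, 1, weight=0.5, r=0.5)
    return g


def matrix_from_values(values: np.ndarray, regions, group="G") -> cn.GroupCorrelationMatrix:
    """GroupCorrelationMatrix straight from an animals x regions value array."""
    r = pd.DataFrame(np.corrcoef(values.T), index=regions, columns=regions)
    return cn.GroupCorrelationMatrix(group=group, regions=list(regions), r=r,
                                     n_animals=values.shape[0])
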