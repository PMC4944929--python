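import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synaptoflow import GeneratorParams, WeightedGraph, generate_sample

#: External supplementary data (not redistributable); the handful of tests
#: that reproduce published whole-sample numbers run only when these files
#: are dropped here.
EXTERNAL_DIR = Path(__file__).resolve().parent.parent / "data" / "external"
S1_ADJACENCY = EXTERNAL_DIR / "s1_adjacency.csv"
RAW_CONTACTS = EXTERNAL_DIR / "raw_contacts.csv"


def graph_from_edges(n, edges, ids=None):
    w = np.zeros((n, n))
    for item in edges:
        a, b, *wt = item
        w[a, b] = w[b, a] = wt[0] if wt else 1.0
    return WeightedGraph(node_ids=ids if ids is not None else np.arange(1, n + 1),
                         weights=w)


@pytest.fixture
def path3():
    """a-b-c path, unit weights, IDs 1..3."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def cycle4():
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def two_dyads():
    return graph_from_edges(4, [(0, 1), (2, 3)])


@pytest.fixture
def two_cliques_bridge():
    """Two 5-cliques joined by one unit link."""
    edges = []
    for s in (0, 5):
        edges += [(a, b) for a in range(s, s + 5) for b in range(a + 1, s + 5)]
    edges.append((4, 5))
    return graph_from_edges(10, edges)


@pytest.fixture
def two_triangles_bridge():
    edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    return graph_from_edges(6, edges)


def random_connected_graph(rng, n, p=0.35, max_weight=5, weight_choices=None):
    """Random weighted graph with no isolated node.

    ``weight_choices`` restricts link weights to a fixed set (e.g. powers of
    two, so that inverse-weight path lengths are exact in floating point and
    geodesic ties are unambiguous).
    """
    while True:
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        mask = rng.random(len(iu)) < p
        if weight_choices is not None:
            wt = rng.choice(np.asarray(weight_choices, dtype=float), len(iu))
        else:
            wt = rng.integers(1, max_weight, len(iu)).astype(float)
        w[iu[mask], ju[mask]] = wt[mask]
        w[ju[mask], iu[mask]] = wt[mask]
        if (w.sum(axis=1) > 0).all():
            return WeightedGraph(node_ids=np.arange(1, n + 1), weights=w)


@pytest.fixture(scope="session")
def default_sample():
    """One synthetic sample at the default study conditions."""
    return generate_sample(GeneratorParams(), seed=11)


@pytest.fixture(scope="session")
def small_params():
    """Reduced neuron counts for fast structural tests."""
    counts = (
        ("GC", 8), ("NFac", 30), ("WFac", 20), ("OffSAC", 4), ("OnSAC", 4),
        ("cBC", 50), ("rBC", 24), ("other", 10),
    )
    return GeneratorParams(class_counts=counts, n_glia=20, n_modules=3)
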