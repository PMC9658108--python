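import networkx as nx
import numpy as np
import pytest

from comorbnet.grouping import CodeLookup, DiagnosisRecord


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint unit-weight triangles — the classic modularity worked
    example: the triangle partition scores q = 0.5 exactly."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")], weight=1.0)
    return g


@pytest.fixture
def toy_lookup() -> CodeLookup:
    """Six codes, four clinical categories; code C5 is not chronic and C6
    maps to no category."""
    return CodeLookup(
        chronic={"C1": True, "C2": True, "C3": True, "C4": True,
                 "C5": False, "C6": True},
        category={"C1": (0, "asthma"), "C2": (1, "rhinitis"),
                  "C3": (2, "otitis"), "C4": (3, "obesity"),
                  "C6": (1, "rhinitis")},
    )


@pytest.fixture
def toy_records() -> list[DiagnosisRecord]:
    """Eight patients across two strata; category membership is hand
    countable (see test_grouping for the enumeration)."""
    rows = [
        ("p1", "M", "0-2", "C1"), ("p1", "M", "0-2", "C2"),
        ("p2", "M", "0-2", "C1"), ("p2", "M", "0-2", "C1"),  # duplicate
        ("p3", "M", "0-2", "C3"),
        ("p4", "M", "0-2", "C4"),
        ("p5", "F", "3-10", "C1"),
        ("p6", "F", "3-10", "C2"), ("p6", "F", "3-10", "C3"),
        ("p7", "F", "3-10", "C4"),
        ("p8", "F", "3-10", "C4"), ("p8", "F", "3-10", "C1"),
    ]
    return [DiagnosisRecord(p, s, b, c) for p, s, b, c in rows]


@pytest.fixture
def random_weighted_graphs():
    """Fifty small Erdos-Renyi graphs with uniform weights, fixed stream."""
    rng = np.random.default_rng(7)
    graphs = []
    for _ in range(50):
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1, weight=1.0)
        graphs.append(g)
    return graphs
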