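from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ppiscreen import Graph, build_graph

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_er_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdos-Renyi-style random simple graph with string node ids."""
    names = [f"v{i:02d}" for i in range(n)]
    pairs = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return build_graph(pairs, isolated_nodes=names)


def graph_to_adj(g: Graph) -> dict[str, set[str]]:
    return {v: set(g.neighbors(v)) for v in g.nodes}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture
def path_graph() -> Graph:
    return build_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def bridged_triangles() -> Graph:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    return build_graph(
        [
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("d", "e"), ("e", "f"), ("d", "f"),
            ("c", "d"),
        ]
    )


def clique_edges(names: list[str]) -> list[tuple[str, str]]:
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
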