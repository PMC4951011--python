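"""Shared fixtures and graph generators for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from seedpath.network_io import InteractionRecord, build_network


def make_network(edges: list[tuple[str, str, int]]) -> nx.Graph:
    """Build a weighted network from (node_a, node_b, score) triples."""
    return build_network([InteractionRecord(a, b, s) for a, b, s in edges])


def random_instance(seed: int) -> tuple[nx.Graph, list[str]]:
    """A random small weighted graph plus 2-5 seed nodes.

    Weights are mostly drawn from {1, 2, 3} so that tied shortest paths
    are common (the interesting case for all-paths counting); occasionally
    the full [1, 850] range is used.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    nodes = [f"N{i:02d}" for i in range(n)]
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = int(rng.integers(n - 1, min(2 * n, len(all_pairs)) + 1))
    chosen = rng.choice(len(all_pairs), size=m, replace=False)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for idx in chosen:
        i, j = all_pairs[int(idx)]
        if rng.random() < 0.7:
            weight = int(rng.integers(1, 4))
        else:
            weight = int(rng.integers(1, 851))
        graph.add_edge(nodes[i], nodes[j], weight=weight)
    k = int(rng.integers(2, 6))
    seeds = [nodes[int(i)] for i in rng.choice(n, size=min(k, n), replace=False)]
    return graph, seeds


@pytest.fixture
def toy_links_text() -> str:
    """Two shortest-path bridges X and Y between three seeds A, B, C."""
    lines = ["protein1 protein2 combined_score"]
    for a, b in [("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "C")]:
        lines.append(f"{a} {b} 999")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_seed_text() -> str:
    return "# seeds\nA\nB\nC\n"
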