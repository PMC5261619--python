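"""Shared fixtures and independent brute-force oracles.

The oracles recompute centralities by explicit enumeration (all shortest
paths listed, triangles counted pairwise) so they stay independent of
the implementation paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from quartetnet import QuartetSpec


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Unnormalized betweenness by listing every shortest path."""
    betw = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                betw[v] += 1.0 / len(paths)
    return betw


def brute_force_closeness(g: nx.Graph) -> dict:
    out = {}
    n = g.number_of_nodes()
    for v in g.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())
        reach = len(dist) - 1
        # Wasserman-Faust generalization for possibly disconnected graphs
        out[v] = (reach / total) * (reach / (n - 1)) if total > 0 and n > 1 else 0.0
    return out


def brute_force_clustering(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def two_cliques_with_bridge(k: int = 10) -> tuple[nx.Graph, str]:
    """Two k-cliques joined only through a planted bridge gene."""
    g = nx.Graph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for block in (left, right):
        g.add_edges_from(itertools.combinations(block, 2))
    bridge = "BRIDGE"
    g.add_edge(bridge, left[0])
    g.add_edge(bridge, right[0])
    return g, bridge


@pytest.fixture
def small_spec() -> QuartetSpec:
    """Scaled-down quartet for fast unit tests."""
    return QuartetSpec(
        seed=7,
        n_variants=300,
        n_genes=150,
        shared_inherited_count=30,
        male_exclusive_count=25,
        female_exclusive_count=20,
        hemizygous_x_count=2,
        de_novo_rate=0.003,
        n_network_genes=40,
    )


@pytest.fixture
def study_spec() -> QuartetSpec:
    """Defaults: the study-scale conditions (102/125/85 partition)."""
    return QuartetSpec(seed=7)
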