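"""Shared fixtures: random layered DAGs and brute-force path oracles."""

from __future__ import annotations

import numpy as np
import pytest

from snnstream.netgraph import LayerNode, NetworkGraph


def make_random_dag(
    rng: np.random.Generator,
    n_nodes: int,
    width: int = 3,
    max_delay: int = 1,
) -> NetworkGraph:
    """Random layered DAG with one input (node 0), one sink (last node),
    every node reachable from the input and reaching the sink.

    Hidden nodes are dense vector layers so the graph doubles as a runnable
    model for perturbation tests.
    """
    assert n_nodes >= 2
    nodes = [LayerNode(0, "input", {"channels": width, "dense": True, "in_channels": width})]
    for i in range(1, n_nodes - 1):
        nodes.append(LayerNode(i, "conv", {"channels": width, "dense": True}))
    nodes.append(LayerNode(n_nodes - 1, "fully-connected", {"classes": 2, "global_pool": True}))
    edges: list[tuple[int, int, int]] = []
    for i in range(1, n_nodes):
        # at least one predecessor among earlier nodes
        preds = {int(rng.integers(0, i))}
        for j in range(i):
            if rng.random() < 0.4:
                preds.add(j)
        for j in sorted(preds):
            edges.append((j, i, int(rng.integers(1, max_delay + 1))))
    # every non-sink node needs a successor: link stragglers to the sink
    have_succ = {s for s, _, _ in edges}
    for i in range(n_nodes - 1):
        if i not in have_succ:
            edges.append((i, n_nodes - 1, int(rng.integers(1, max_delay + 1))))
    return NetworkGraph(nodes, edges)


def enumerate_path_lengths(graph: NetworkGraph) -> list[int]:
    """All delay-weighted input-to-output simple-path lengths by recursive DFS."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for s, t, d in graph.edges:
        adj.setdefault(s, []).append((t, d))
    out = graph.output_id
    lengths: list[int] = []

    def walk(node: int, acc: int) -> None:
        if node == out:
            lengths.append(acc)
            return
        for t, d in adj.get(node, []):
            walk(t, acc + d)

    walk(graph.input_id, 0)
    return lengths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
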