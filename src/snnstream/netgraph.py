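"""Layered network graphs, streaming rollouts and their temporal path statistics.

A network graph is a DAG whose nodes are whole layers (the initial convolution,
dense-block layers, transitions, the global-pool + fully-connected classifier)
and whose edges carry an axonal delay ``d_ann`` measured in rollout frames.  In
a *streaming rollout* every edge -- including plain feed-forward ones -- spans
at least one rollout frame, so every layer can update in parallel from the
previous frame's state, exactly as a model-parallel spiking network would.

Input frames are injected at the initial convolution node; path lengths are
therefore measured from that node to the classifier node.  The spread between
the longest and the shortest input-to-output path sets the spatio-temporal
receptive field ``tau = l_max - l_s + 1``: an output merges information from
``tau`` consecutive input frames that arrive simultaneously over paths of
different depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import networkx as nx

__all__ = [
    "LayerNode",
    "NetworkGraph",
    "PathStats",
    "RolloutSchedule",
    "build_densenet_graph",
    "fig_example_graph",
    "chain_graph",
    "path_stats",
    "rollout",
    "dependency_cone",
]

NODE_KINDS = ("input", "conv", "transition", "global-pool", "fully-connected")


@dataclass(frozen=True)
class LayerNode:
    """One layer of the network.

    ``kind == "input"`` marks the entry layer: it receives the external input
    frame directly (no delayed predecessors) and applies the initial
    convolution.  ``params`` holds layer hyperparameters such as ``channels``,
    ``kernel``, ``pool`` (for transitions) or ``classes`` (for the terminal
    fully-connected node).
    """

    id: int
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass
class NetworkGraph:
    """DAG of :class:`LayerNode` with per-edge delays in rollout frames."""

    nodes: list[LayerNode]
    edges: list[tuple[int, int, int]]  # (source id, target id, delay d_ann >= 1)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        known = set(ids)
        for s, t, d in self.edges:
            if s not in known or t not in known:
                raise ValueError(f"edge ({s}, {t}) references unknown node")
            if d < 0:
                raise ValueError(f"edge ({s}, {t}) has negative delay {d}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("network graph must be acyclic")
        n_in = sum(1 for n in self.nodes if n.kind == "input")
        if n_in != 1:
            raise ValueError(f"expected exactly one input node, found {n_in}")

    # -- structure helpers -------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, **n.params)
        for s, t, d in self.edges:
            g.add_edge(s, t, delay=d)
        return g

    @property
    def input_id(self) -> int:
        return next(n.id for n in self.nodes if n.kind == "input")

    @property
    def output_id(self) -> int:
        """The unique sink node (the classifier)."""
        targets = {t for _, t, _ in self.edges}
        sources = {s for s, _, _ in self.edges}
        sinks = [n.id for n in self.nodes if n.id not in sources and (n.id in targets or len(self.nodes) == 1)]
        if len(sinks) != 1:
            raise ValueError(f"expected exactly one output node, found {sinks}")
        return sinks[0]

    def node(self, node_id: int) -> LayerNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def predecessors(self, node_id: int) -> list[int]:
        """Predecessor ids in ascending-id order (fixed concatenation order)."""
        return sorted(s for s, t, _ in self.edges if t == node_id)

    def successors(self, node_id: int) -> list[int]:
        return sorted(t for s, t, _ in self.edges if s == node_id)

    def topological_order(self) -> list[int]:
        """Deterministic topological order, ties broken by node id."""
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    @property
    def depth(self) -> int:
        """Number of block convolutions plus the initial convolution.

        For a DenseNet graph this is ``n_layers * n_blocks + 1``; transition
        and classifier layers are not counted.
        """
        return sum(1 for n in self.nodes if n.kind in ("input", "conv"))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        order = self.topological_order()
        pos = {nid: i for i, nid in enumerate(order)}
        doc = {
            "nodes": [
                {"id": n.id, "kind": n.kind, "params": n.params}
                for n in sorted(self.nodes, key=lambda n: pos[n.id])
            ],
            "edges": [
                {"source": s, "target": t, "delay": d}
                for s, t, d in sorted(self.edges, key=lambda e: (pos[e[0]], pos[e[1]]))
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkGraph":
        doc = json.loads(text)
        nodes = [LayerNode(n["id"], n["kind"], dict(n["params"])) for n in doc["nodes"]]
        edges = [(e["source"], e["target"], int(e["delay"])) for e in doc["edges"]]
        return cls(nodes, edges)


@dataclass(frozen=True)
class PathStats:
    """Extremal delay-weighted input-to-output path lengths of a graph.

    ``tau = l_max - l_s + 1`` is the receptive-field duration in input frames:
    an output at rollout frame ``k`` can merge inputs injected at frames
    ``k - l_max .. k - l_s``.
    """

    l_s: int
    l_max: int
    tau: int
    depth: int


def path_stats(graph: NetworkGraph) -> PathStats:
    """Shortest/longest delay-weighted paths from the input node to the output.

    With all delays equal to one the path length is simply the edge count.
    """
    g = graph.to_networkx()
    src, dst = graph.input_id, graph.output_id
    for nid in g.nodes:
        if nid != src and not nx.has_path(g, src, nid):
            raise ValueError(f"node {nid} not reachable from input")
        if nid != dst and not nx.has_path(g, nid, dst):
            raise ValueError(f"output not reachable from node {nid}")
    if src == dst:
        return PathStats(l_s=0, l_max=0, tau=1, depth=graph.depth)
    l_s = nx.shortest_path_length(g, src, dst, weight="delay")
    # longest path via DP over a topological order (delays are non-negative)
    longest: dict[int, float] = {src: 0}
    for nid in nx.topological_sort(g):
        if nid not in longest:
            continue
        for succ in g.successors(nid):
            cand = longest[nid] + g.edges[nid, succ]["delay"]
            if cand > longest.get(succ, float("-inf")):
                longest[succ] = cand
    l_max = int(longest[dst])
    return PathStats(l_s=int(l_s), l_max=l_max, tau=l_max - int(l_s) + 1, depth=graph.depth)


@dataclass
class RolloutSchedule:
    """Assignment of input frames, node updates and outputs to rollout frames.

    Frames are 1-indexed.  ``input_slot[i]`` is the rollout frame at which
    input frame ``i`` is injected; with ``N >= tau`` input frame ``i`` feeds
    rollout frame ``i`` and the rollout spans ``K = N + l_s`` frames, so the
    last output (frame ``K``) is connected to the last input via the shortest
    path.  Outputs are emitted at frames ``l_s + 1 .. K``.
    """

    K: int
    N: int
    stats: PathStats
    input_slot: dict[int, int]
    output_frames: list[int]
    node_earliest: dict[int, int]  # first rollout frame at which a node can be active
    path_lengths: frozenset[int] = frozenset()  # realizable input->output path delays

    def active_nodes(self, k: int) -> list[int]:
        """Node ids that update at rollout frame ``k`` (warm-up cone respected)."""
        return sorted(nid for nid, e in self.node_earliest.items() if e <= k)


def rollout(graph: NetworkGraph, n_frames: int) -> RolloutSchedule:
    """Build the streaming-rollout schedule of ``graph`` for ``n_frames`` inputs.

    When ``n_frames`` is smaller than the receptive field ``tau``, the inputs
    are spread evenly over the ``tau`` input slots of the fixed rollout
    (input ``i`` lands in slot ``round(i * tau / N)``) and the rollout keeps
    its full ``tau + l_s`` frames.
    """
    if n_frames < 1:
        raise ValueError("need at least one input frame")
    stats = path_stats(graph)
    if n_frames >= stats.tau:
        slots = {i: i for i in range(1, n_frames + 1)}
        n_slots = n_frames
    else:
        slots = {i: round(i * stats.tau / n_frames) for i in range(1, n_frames + 1)}
        n_slots = stats.tau
    K = n_slots + stats.l_s
    # earliest possible activity per node: first filled slot + shortest
    # delay-weighted distance from the input node
    g = graph.to_networkx()
    dist = nx.shortest_path_length(g, graph.input_id, weight="delay")
    first_slot = min(slots.values())
    node_earliest = {nid: first_slot + int(d) for nid, d in dist.items()}
    # realizable delay-weighted path lengths input -> output (DP over topo order)
    lens: dict[int, set[int]] = {graph.input_id: {0}}
    for nid in nx.topological_sort(g):
        if nid not in lens:
            continue
        for succ in g.successors(nid):
            d = g.edges[nid, succ]["delay"]
            lens.setdefault(succ, set()).update(v + d for v in lens[nid])
    return RolloutSchedule(
        K=K,
        N=n_frames,
        stats=stats,
        input_slot=slots,
        output_frames=list(range(stats.l_s + 1, K + 1)),
        node_earliest=node_earliest,
        path_lengths=frozenset(lens[graph.output_id]),
    )


def dependency_cone(schedule: RolloutSchedule, output_frame: int) -> set[int]:
    """Input frames that can influence the output at rollout frame ``k``.

    Data injected at slot ``s`` arrives at the output at frames ``s + l`` for
    every realizable path length ``l`` (``l_s <= l <= l_max``; for densely
    connected graphs every length in between is realizable, so the cone is
    the contiguous window ``k - l_max .. k - l_s``).
    """
    if output_frame not in schedule.output_frames:
        raise ValueError(f"frame {output_frame} is not an output frame of this rollout")
    return {
        i
        for i, s in schedule.input_slot.items()
        if (output_frame - s) in schedule.path_lengths
    }


# ---------------------------------------------------------------------------
# Graph constructors
# ---------------------------------------------------------------------------


def build_densenet_graph(
    n_blocks: int,
    n_layers: int,
    growth: int,
    input_spec: tuple[int, int, int] = (2, 16, 16),
    n_classes: int = 2,
) -> NetworkGraph:
    """DenseNet-style network graph: initial conv, densely connected blocks,
    3x3-conv + average-pooling transitions, global-average-pool and FC output.

    Within a block the block input connects to every layer and every layer to
    all later layers; the block's concatenation -- block input plus all layer
    outputs -- feeds the next transition (or, after the last block, the
    global-pool node, which feeds the fully-connected classifier).  Each block
    thus contributes paths of length 1..n_layers+1 and the terminal pool+FC
    chain adds 2, so l_s = n_blocks + 1 and l_max = n_blocks*(n_layers+1) + 1,
    giving a receptive field tau = n_blocks*n_layers + 1 equal to the depth
    ``D = n_layers * n_blocks + 1``.  All edges carry delay 1.
    """
    if n_blocks < 1 or n_layers < 1 or growth < 1:
        raise ValueError("n_blocks, n_layers and growth must all be >= 1")
    c_in, h, w = input_spec
    # spatial bookkeeping: each transition halves the resolution
    for b in range(n_blocks - 1):
        if h < 2 or w < 2 or h % 2 or w % 2:
            raise ValueError(
                f"spatial size underflow: {h}x{w} cannot be average-pooled at "
                f"transition {b + 1} (need even sizes >= 2); reduce n_blocks or "
                "enlarge the input"
            )
        h //= 2
        w //= 2

    nodes: list[LayerNode] = []
    edges: list[tuple[int, int, int]] = []
    nid = 0
    nodes.append(LayerNode(nid, "input", {"channels": growth, "kernel": 3, "in_channels": c_in}))
    block_input = nid
    nid += 1
    for b in range(n_blocks):
        layers: list[int] = []
        for _ in range(n_layers):
            nodes.append(LayerNode(nid, "conv", {"channels": growth, "kernel": 3}))
            for prev in [block_input] + layers:
                edges.append((prev, nid, 1))
            layers.append(nid)
            nid += 1
        last_block = b == n_blocks - 1
        if last_block:
            nodes.append(LayerNode(nid, "global-pool", {}))
        else:
            nodes.append(LayerNode(nid, "transition", {"channels": growth, "kernel": 3, "pool": 2}))
        for prev in [block_input] + layers:
            edges.append((prev, nid, 1))
        block_input = nid
        nid += 1
    nodes.append(LayerNode(nid, "fully-connected", {"classes": n_classes}))
    edges.append((nid - 1, nid, 1))
    return NetworkGraph(nodes, edges)


def fig_example_graph(growth: int = 8, input_spec: tuple[int, int, int] = (2, 16, 16)) -> NetworkGraph:
    """The canonical single-block example graph: an initial convolution (where
    frames are injected), one block of three densely connected conv layers,
    and a fully-connected classifier fed by all three block layers.

    Shortest input-to-output path l_s = 2 (conv1 -> layer 4 -> FC), longest
    l_max = 4 (conv1 -> 2 -> 3 -> 4 -> FC), receptive field tau = 3.
    """
    c = int(input_spec[0])
    nodes = [LayerNode(0, "input", {"channels": growth, "kernel": 3, "in_channels": c})]
    edges: list[tuple[int, int, int]] = []
    for i in (1, 2, 3):
        nodes.append(LayerNode(i, "conv", {"channels": growth, "kernel": 3}))
        for prev in range(i):
            edges.append((prev, i, 1))
    nodes.append(LayerNode(4, "fully-connected", {"classes": 2, "global_pool": True}))
    for prev in (1, 2, 3):
        edges.append((prev, 4, 1))
    return NetworkGraph(nodes, edges)


def chain_graph(n_edges: int, width: int = 4, n_classes: int = 2) -> NetworkGraph:
    """A pure chain with ``n_edges`` edges (l_s = l_max = n_edges, tau = 1).

    Hidden nodes are dense (vector) layers; useful for latency/delay tests.
    """
    if n_edges < 1:
        raise ValueError("need at least one edge")
    nodes = [LayerNode(0, "input", {"channels": width, "dense": True, "in_channels": width})]
    edges = []
    for i in range(1, n_edges):
        kind = "conv"
        nodes.append(LayerNode(i, kind, {"channels": width, "dense": True}))
        edges.append((i - 1, i, 1))
    out = n_edges
    nodes.append(LayerNode(out, "fully-connected", {"classes": n_classes, "global_pool": True}))
    edges.append((out - 1, out, 1))
    return NetworkGraph(nodes, edges)
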