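"""Degree-limited prediction and similarity networks.

A readable figure-style network keeps only the strongest edges: candidates
passing the FDR (or |similarity|) cutoff are inserted in descending weight
order, skipping any edge that would push either endpoint past the per-node
degree cap (default 3).  Edges corroborated by prior knowledge are flagged
so novel predictions stand out, and components consisting entirely of known
edges can be trimmed away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class Edge:
    node_a: str
    node_b: str
    weight: float
    known: bool = False
    layer_a: str = ""
    layer_b: str = ""


@dataclass
class PredictionNetwork:
    """Weighted undirected graph with a per-node degree cap."""

    edges: list = field(default_factory=list)
    node_kinds: dict = field(default_factory=dict)  # label -> kind
    max_edges_per_node: int = 3

    def __post_init__(self) -> None:
        degs = self.degrees()
        over = {n: d for n, d in degs.items() if d > self.max_edges_per_node}
        if over:
            raise ValueError(f"degree cap violated: {over}")
        seen = set()
        for e in self.edges:
            if e.node_a == e.node_b:
                raise ValueError(f"self-loop at {e.node_a!r}")
            key = frozenset((e.node_a, e.node_b))
            if key in seen:
                raise ValueError(f"duplicate edge {e.node_a!r}-{e.node_b!r}")
            seen.add(key)

    def degrees(self) -> dict:
        degs: dict = {}
        for e in self.edges:
            degs[e.node_a] = degs.get(e.node_a, 0) + 1
            degs[e.node_b] = degs.get(e.node_b, 0) + 1
        return degs

    def max_degree(self) -> int:
        degs = self.degrees()
        return max(degs.values()) if degs else 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, kind in self.node_kinds.items():
            g.add_node(node, kind=kind)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, weight=e.weight, known=e.known)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.node_a, e.node_b, e.weight, e.known, e.layer_a, e.layer_b)
                for e in self.edges
            ],
            columns=["node_a", "node_b", "weight", "known", "layer_a", "layer_b"],
        )

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _norm_pair(a, b):
    return (a, b) if str(a) <= str(b) else (b, a)


def build_network(
    predictions,
    fdr_cutoff: "float | None" = None,
    max_edges_per_node: int = 3,
    known_edges=(),
    similarity_cutoff: "float | None" = None,
    node_kinds: "dict | None" = None,
) -> PredictionNetwork:
    """Greedy degree-capped network construction.

    ``predictions`` is either a list of pair-subject ``ScoredPrediction``
    objects (filtered by ``estimated_fdr <= fdr_cutoff``) or an iterable of
    ``(node_a, node_b, weight)`` similarity edges (filtered by
    ``|weight| >= similarity_cutoff``).  Surviving edges are inserted in
    descending |weight| order; an edge is skipped when either endpoint has
    already reached ``max_edges_per_node``.  Pairs present in
    ``known_edges`` are flagged known.
    """
    if max_edges_per_node <= 0:
        raise ValueError("max_edges_per_node must be positive")
    if fdr_cutoff is not None and not (0 <= fdr_cutoff <= 1):
        raise ValueError("fdr_cutoff must lie in [0, 1]")

    known = {frozenset(_norm_pair(a, b)) for a, b in known_edges}
    candidates = []
    for item in predictions:
        if hasattr(item, "subject"):  # ScoredPrediction over a pair
            a, b = item.subject
            if fdr_cutoff is not None and item.estimated_fdr > fdr_cutoff:
                continue
            candidates.append((a, b, float(item.score)))
        else:
            a, b, w = item
            if similarity_cutoff is not None and abs(w) < similarity_cutoff:
                continue
            candidates.append((a, b, float(w)))
    if not candidates:
        warnings.warn("no edge survives the cutoff; returning an empty network")
        return PredictionNetwork(max_edges_per_node=max_edges_per_node)

    candidates.sort(key=lambda t: (-abs(t[2]), str(t[0]), str(t[1])))
    degs: dict = {}
    seen = set()
    edges = []
    for a, b, w in candidates:
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        if degs.get(a, 0) >= max_edges_per_node or degs.get(b, 0) >= max_edges_per_node:
            continue
        seen.add(key)
        degs[a] = degs.get(a, 0) + 1
        degs[b] = degs.get(b, 0) + 1
        edges.append(Edge(a, b, w, known=key in known))
    return PredictionNetwork(
        edges=edges,
        node_kinds=dict(node_kinds or {}),
        max_edges_per_node=max_edges_per_node,
    )


def trim_known_clusters(net: PredictionNetwork) -> PredictionNetwork:
    """Drop every connected component whose edges are all already known,
    leaving only components that contain at least one novel prediction."""
    g = net.to_networkx()
    keep_nodes = set()
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        if sub.number_of_edges() == 0:
            continue
        if not all(d["known"] for _, _, d in sub.edges(data=True)):
            keep_nodes.update(component)
    edges = [e for e in net.edges if e.node_a in keep_nodes and e.node_b in keep_nodes]
    kinds = {n: k for n, k in net.node_kinds.items() if n in keep_nodes}
    return PredictionNetwork(
        edges=edges, node_kinds=kinds, max_edges_per_node=net.max_edges_per_node
    )


def tripartite_join(
    left_edges,
    middle_right_edges,
    max_edges_per_node: int = 3,
    layers=("left", "middle", "right"),
) -> PredictionNetwork:
    """Join two bipartite edge lists sharing a middle layer into one
    three-layer network (e.g. drug - enzyme - disease paths).

    Middle nodes lacking a partner on either side are dropped (and
    counted in the returned network's ``node_kinds`` via absence); the
    degree cap applies per layer pairing.
    """
    left_edges = [(a, m, float(w)) for a, m, w in left_edges]
    middle_right_edges = [(m, b, float(w)) for m, b, w in middle_right_edges]
    mid_left = {m for _, m, _ in left_edges}
    mid_right = {m for m, _, _ in middle_right_edges}
    shared = mid_left & mid_right
    if not shared:
        raise ValueError("no shared middle-layer labels between the two edge lists")
    n_dropped = len((mid_left | mid_right) - shared)

    l_net = build_network(
        [(a, m, w) for a, m, w in left_edges if m in shared],
        max_edges_per_node=max_edges_per_node,
    )
    r_net = build_network(
        [(m, b, w) for m, b, w in middle_right_edges if m in shared],
        max_edges_per_node=max_edges_per_node,
    )
    kinds: dict = {}
    edges = []
    for e in l_net.edges:
        kinds[e.node_a] = layers[0]
        kinds[e.node_b] = layers[1]
        edges.append(Edge(e.node_a, e.node_b, e.weight, layer_a=layers[0], layer_b=layers[1]))
    for e in r_net.edges:
        kinds[e.node_a] = layers[1]
        kinds[e.node_b] = layers[2]
        edges.append(Edge(e.node_a, e.node_b, e.weight, layer_a=layers[1], layer_b=layers[2]))
    net = PredictionNetwork(
        edges=edges, node_kinds=kinds, max_edges_per_node=2 * max_edges_per_node
    )
    net.n_dropped_middle = n_dropped
    return net
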