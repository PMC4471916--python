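"""Song transition networks and the two orderliness metrics.

A sequence of song types is translated into a directed graph with types as
nodes and observed adjacent transitions as edges.  Two metrics summarise how
ordered the singing is:

* **average shortest path length** — mean hop-count geodesic over ordered
  reachable node pairs; long linear singing sequences inflate it;
* **transitivity** — the global clustering coefficient of the undirected
  projection, i.e. the probability that two neighbours of a node are
  themselves connected.

Metrics are computed on unweighted edges; transition counts are retained for
reporting/export only.  Immediate repetitions of the same type (self-loops)
are dropped by default.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import TYPE_CHECKING

from .errors import IntegrityError, MetricUndefinedError

if TYPE_CHECKING:  # pragma: no cover
    from .song_corpus import SongSequence


@dataclass(frozen=True)
class TransitionNetwork:
    nodes: tuple[str, ...]
    edge_counts: dict[tuple[str, str], int]
    self_loops_dropped: bool

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_counts)

    def successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {u: [] for u in self.nodes}
        for (u, v) in self.edge_counts:
            adj[u].append(v)
        return adj

    def undirected_neighbors(self) -> dict[str, set[str]]:
        """Undirected, self-loop-free projection used for transitivity."""
        nbrs: dict[str, set[str]] = {u: set() for u in self.nodes}
        for (u, v) in self.edge_counts:
            if u != v:
                nbrs[u].add(v)
                nbrs[v].add(u)
        return nbrs


@dataclass(frozen=True)
class NetworkMetrics:
    average_shortest_path: float
    transitivity: float
    n_nodes: int
    n_edges: int
    fraction_reachable_pairs: float


def build_network(seq: "SongSequence", drop_self_loops: bool = True) -> TransitionNetwork:
    """Directed, count-weighted transition network of a song sequence.

    Nodes are the distinct song types of the sequence; an edge (u, v) records
    every adjacent pair where v immediately follows u.  With
    ``drop_self_loops`` (default), transitions between identical consecutive
    types are discarded.
    """
    types = seq.types
    if len(types) < 2:
        raise IntegrityError(
            f"male {seq.male_id!r}: need at least 2 songs to build a network"
        )
    counts: dict[tuple[str, str], int] = {}
    for u, v in zip(types, types[1:]):
        if drop_self_loops and u == v:
            continue
        counts[(u, v)] = counts.get((u, v), 0) + 1
    # node set = distinct types in order of first appearance
    seen: dict[str, None] = {}
    for t in types:
        seen.setdefault(t)
    return TransitionNetwork(
        nodes=tuple(seen), edge_counts=counts, self_loops_dropped=drop_self_loops
    )


def _bfs_distances(adj: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def average_shortest_path(net: TransitionNetwork) -> tuple[float, float]:
    """Mean geodesic hop count over ordered reachable pairs.

    Returns ``(mean, fraction_reachable_pairs)``.  Unreachable ordered pairs
    are excluded from the mean (the fraction reports how many pairs entered
    it).  Raises :class:`MetricUndefinedError` on an edgeless network.
    """
    if net.n_nodes < 2:
        raise MetricUndefinedError("average shortest path needs >= 2 nodes")
    if net.n_edges == 0:
        raise MetricUndefinedError("average shortest path undefined: no edges")
    adj = net.successors()
    total = 0
    reachable = 0
    for u in net.nodes:
        dist = _bfs_distances(adj, u)
        for v, d in dist.items():
            if v != u:
                total += d
                reachable += 1
    n = net.n_nodes
    ordered_pairs = n * (n - 1)
    if reachable == 0:
        raise MetricUndefinedError("no reachable ordered pairs")
    return total / reachable, reachable / ordered_pairs


def transitivity(net: TransitionNetwork) -> float:
    """Global clustering coefficient of the undirected projection.

    3 x triangles / connected triples, equivalently the fraction of
    neighbour pairs of each node that are themselves connected, pooled over
    nodes.  Raises :class:`MetricUndefinedError` when no connected triples
    exist (never a silent 0).
    """
    if net.n_nodes < 3:
        raise MetricUndefinedError("transitivity needs >= 3 nodes")
    nbrs = net.undirected_neighbors()
    triples = 0
    closed = 0
    for u in net.nodes:
        nu = nbrs[u]
        deg = len(nu)
        triples += deg * (deg - 1) // 2
        for a, b in combinations(sorted(nu), 2):
            if b in nbrs[a]:
                closed += 1
    if triples == 0:
        raise MetricUndefinedError("transitivity undefined: no connected triples")
    return closed / triples


def network_metrics(
    seq: "SongSequence", drop_self_loops: bool = True
) -> NetworkMetrics:
    """Build the network and compute both orderliness metrics."""
    net = build_network(seq, drop_self_loops=drop_self_loops)
    aspl, frac = average_shortest_path(net)
    trans = transitivity(net)
    return NetworkMetrics(
        average_shortest_path=aspl,
        transitivity=trans,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        fraction_reachable_pairs=frac,
    )


def write_edgelist(net: TransitionNetwork, path: str | Path, sep: str = "\t") -> None:
    """Export as delimited text: source, target, count."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(("source", "target", "count")) + "\n")
        for (u, v), c in sorted(net.edge_counts.items()):
            fh.write(sep.join((u, v, str(c))) + "\n")


def to_networkx(net: TransitionNetwork):
    """Directed networkx graph with ``count`` edge attributes (for export)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for (u, v), c in net.edge_counts.items():
        g.add_edge(u, v, count=c)
    return g


def write_graphml(net: TransitionNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)
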