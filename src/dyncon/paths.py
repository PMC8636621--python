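"""Optimal and suboptimal allosteric path enumeration.

On a −ln|correlation|-weighted residue network the minimum-weight path
between a source and target residue is the dominant communication route;
the bundle of lowest-weight *suboptimal* paths around it traces the wider
allosteric channel.  Suboptimal enumeration follows the SOAN recipe: the
graph is first reduced to nodes within a small hop radius (default 2) of
the optimal path, then the k lowest-weight simple paths are enumerated
inside the reduced graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .networks import WeightedNetwork

__all__ = [
    "PathSet",
    "NoPathError",
    "optimal_path",
    "soan_suboptimal_paths",
    "path_composition",
]

_EPS = 1e-9


class NoPathError(LookupError):
    """Source and target are not connected."""


@dataclass
class PathSet:
    """Ranked optimal + suboptimal paths between two residues."""

    source: int
    target: int
    paths: list[tuple[float, tuple]]     # (total weight, node sequence)
    k: int
    hop_radius: int | None = None
    reduced_nodes: frozenset = frozenset()

    def __post_init__(self) -> None:
        for w, p in self.paths:
            if p[0] != self.source or p[-1] != self.target:
                raise ValueError("path does not join source and target")
            if len(set(p)) != len(p):
                raise ValueError("paths must be simple")
        weights = [w for w, _ in self.paths]
        if any(b < a - _EPS for a, b in zip(weights, weights[1:])):
            raise ValueError("paths must be sorted by nondecreasing weight")

    def __len__(self) -> int:
        return len(self.paths)

    def to_tsv(self, path: str, labels: dict[int, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tweight\tpath\n")
            for rank, (w, p) in enumerate(self.paths, start=1):
                seq = "-".join((labels or {}).get(n, str(n)) for n in p)
                fh.write(f"{rank}\t{w:.6f}\t{seq}\n")


def _graph_of(network: WeightedNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, WeightedNetwork) else network


def _path_weight(g: nx.Graph, path) -> float:
    return float(sum(g[u][v]["weight"] for u, v in zip(path, path[1:])))


def optimal_path(
    network: WeightedNetwork | nx.Graph, source: int, target: int
) -> tuple[list, float]:
    """Minimum-weight simple path; ties broken lexicographically.

    Weights are nonnegative, so some shortest path is always simple; among
    all minimum-weight simple paths the lexicographically smallest node
    sequence is returned for determinism (relevant when zero-weight edges
    create ties).
    """
    g = _graph_of(network)
    if source == target:
        raise ValueError("source and target must differ")
    for n in (source, target):
        if n not in g:
            raise KeyError(f"node {n!r} not in network")
    try:
        dist_t = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    except nx.NetworkXNoPath:  # pragma: no cover
        raise NoPathError(f"no path between {source} and {target}")
    if source not in dist_t:
        raise NoPathError(f"no path between {source} and {target}")
    w_min = dist_t[source]
    tol = _EPS * max(1.0, w_min)

    # DFS over the optimal subgraph, visiting neighbours in ascending order,
    # returns the lexicographically smallest minimum-weight simple path.
    path = [source]
    on_path = {source}

    def dfs(u, acc) -> bool:
        if u == target:
            return abs(acc - w_min) <= tol
        for v in sorted(g.neighbors(u)):
            if v in on_path or v not in dist_t:
                continue
            w = g[u][v]["weight"]
            if acc + w + dist_t[v] > w_min + tol:
                continue
            path.append(v)
            on_path.add(v)
            if dfs(v, acc + w):
                return True
            path.pop()
            on_path.remove(v)
        return False

    if not dfs(source, 0.0):  # pragma: no cover - guaranteed reachable
        raise NoPathError(f"no path between {source} and {target}")
    return list(path), w_min


def k_shortest_simple_paths(
    graph: nx.Graph, source: int, target: int, k: int
) -> list[tuple[float, tuple]]:
    """k lowest-weight simple paths, sorted by (weight, node sequence).

    Built on deviation-based (Yen) enumeration; the tie group straddling
    the k-th weight is collected in full before sorting so truncation is
    deterministic.
    """
    out: list[tuple[float, tuple]] = []
    try:
        gen = nx.shortest_simple_paths(graph, source, target, weight="weight")
        for p in gen:
            w = _path_weight(graph, p)
            if len(out) >= k and w > out[k - 1][0] + _EPS:
                break
            out.append((w, tuple(p)))
            out.sort(key=lambda t: (t[0], t[1]))
    except nx.NetworkXNoPath:
        raise NoPathError(f"no path between {source} and {target}")
    return out[:k]


def soan_suboptimal_paths(
    network: WeightedNetwork | nx.Graph,
    source: int,
    target: int,
    k: int = 5000,
    hop_radius: int = 2,
) -> PathSet:
    """Optimal + suboptimal paths with hop-radius graph reduction.

    The graph is reduced to nodes within ``hop_radius`` hops (unweighted)
    of any node on the optimal path; the k lowest-weight simple paths are
    then enumerated inside that reduced graph.  Low-weight detours through
    nodes farther than the hop radius are — by construction — absent; this
    is the documented efficiency/completeness trade-off of the reduction.
    """
    g = _graph_of(network)
    opt, w_opt = optimal_path(g, source, target)
    keep = set(opt)
    frontier = set(opt)
    for _ in range(max(0, hop_radius)):
        nxt = set()
        for u in frontier:
            nxt |= set(g.neighbors(u))
        nxt -= keep
        keep |= nxt
        frontier = nxt
    sub = g.subgraph(keep)
    paths = k_shortest_simple_paths(sub, source, target, k)
    return PathSet(source=source, target=target, paths=paths, k=k,
                   hop_radius=hop_radius, reduced_nodes=frozenset(keep))


def path_composition(
    pathset: PathSet,
    query: set | None = None,
    network: WeightedNetwork | nx.Graph | None = None,
    include_neighbors: bool = False,
):
    """Per-node path frequency, and the on-path fraction of a query set.

    A query residue is "on-path" when it lies on at least one path (or,
    with ``include_neighbors``, is adjacent in the network to a path node).
    Query nodes absent from the paths' node universe count as off-path.
    """
    if len(pathset) == 0:
        raise ValueError("empty path set")
    freq: dict[int, int] = {}
    for _, p in pathset.paths:
        for n in p:
            freq[n] = freq.get(n, 0) + 1
    result = {"node_frequency": freq, "on_path_fraction": None,
              "on_path_nodes": None}
    if query is not None:
        query = set(query)
        if not query:
            raise ValueError("empty query set")
        covered = set(freq)
        if include_neighbors:
            if network is None:
                raise ValueError("include_neighbors requires the network")
            g = _graph_of(network)
            extra = set()
            for n in covered:
                if n in g:
                    extra |= set(g.neighbors(n))
            covered |= extra
        universe = set(freq)
        if network is not None:
            universe = set(_graph_of(network).nodes)
        missing = query - universe
        if missing:
            warnings.warn(f"{len(missing)} query node(s) absent from the "
                          "network; counted as off-path")
        on = query & covered
        result["on_path_fraction"] = len(on) / len(query)
        result["on_path_nodes"] = sorted(on)
    return result
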