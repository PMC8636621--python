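"""Correlation-weighted dynamic networks.

Nodes are residues; an edge joins two residues whose heavy atoms stay in
contact for more than a persistence fraction of the trajectory, and carries
weight

    w_ij = -ln |c_ij|,

where c_ij is the Pearson cross-correlation of the residues' node-atom
displacement vectors about their time-averaged positions.  Strongly
correlated contacts are therefore "short" and allosteric signalling is
modelled as shortest/suboptimal paths through the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._geom import superpose_frames
from .contacts import ContactMap
from .structure import Ensemble

__all__ = [
    "CorrelationMatrix",
    "WeightedNetwork",
    "cross_correlation",
    "build_dynamic_network",
    "edge_betweenness",
]


@dataclass
class CorrelationMatrix:
    """Residue–residue cross-correlation of positional fluctuations."""

    residue_index: np.ndarray   # (N,) global residue indices
    matrix: np.ndarray          # (N, N) in [-1, 1]
    node_atom: str = "ca_p"

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class WeightedNetwork:
    """Undirected residue graph with -ln|c| edge weights."""

    graph: nx.Graph
    labels: dict[int, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_edgelist_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("nodeA\tlabelA\tnodeB\tlabelB\tweight\tcorrelation\n")
            for u, v, data in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{self.labels.get(u, u)}\t{v}\t"
                         f"{self.labels.get(v, v)}\t{data['weight']:.6f}\t"
                         f"{data.get('correlation', float('nan')):.6f}\n")

    @classmethod
    def read_edgelist_tsv(cls, path: str) -> "WeightedNetwork":
        g = nx.Graph()
        labels: dict[int, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("nodeA"):
                raise ValueError(f"{path} is not a dyncon edge-list TSV")
            for line in fh:
                ua, la, vb, lb, w, c = line.rstrip("\n").split("\t")
                u, v = int(ua), int(vb)
                labels[u], labels[v] = la, lb
                g.add_edge(u, v, weight=float(w), correlation=float(c))
        return cls(graph=g, labels=labels, provenance={"source": path})

    def write_graphml(self, path: str) -> None:
        g = nx.Graph()
        for u in self.graph.nodes:
            g.add_node(u, label=self.labels.get(u, str(u)))
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(u, v, weight=float(data["weight"]),
                       correlation=float(data.get("correlation", np.nan)))
        nx.write_graphml(g, path)


def cross_correlation(
    ensemble: Ensemble,
    node_atom: str = "ca_p",
    scope: np.ndarray | None = None,
    superpose_iterations: int = 2,
) -> CorrelationMatrix:
    """Pearson cross-correlation of node-atom fluctuations, Δr = r − ⟨r⟩.

    Frames are least-squares superposed onto the (iterated) ensemble mean
    of the node atoms first, so rigid-body drift does not masquerade as
    internal correlation.  Residues with zero fluctuation get undefined
    off-diagonal correlations, reported as 0 with a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("cross-correlation requires at least two frames")
    top = ensemble.topology
    if scope is None:
        scope = np.nonzero(top.polymer != "other")[0]
    scope = np.asarray(sorted(scope), dtype=int)
    if node_atom == "centroid":
        traj = np.array([top.node_positions(f, "centroid")[scope]
                         for f in ensemble.frames])
    else:
        atoms = top.node_atom_indices(node_atom)[scope]
        traj = ensemble.frames[:, atoms, :]
    traj = superpose_frames(traj, iterations=superpose_iterations)
    delta = traj - traj.mean(axis=0, keepdims=True)      # (T, N, 3)
    cov = np.einsum("tid,tjd->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-24
    if zero.any():
        warnings.warn(f"{int(zero.sum())} residue(s) with zero fluctuation; "
                      "their correlations are undefined and set to 0")
    denom = np.sqrt(np.where(zero, 1.0, var))
    c = cov / denom[:, None] / denom[None, :]
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, np.where(zero, 0.0, 1.0))
    c = np.clip(c, -1.0, 1.0)
    return CorrelationMatrix(residue_index=scope, matrix=c, node_atom=node_atom)


def build_dynamic_network(
    cmap: ContactMap,
    corr: CorrelationMatrix,
    persistence: float = 0.75,
) -> WeightedNetwork:
    """Graph with an edge wherever p_ij > persistence and c_ij ≠ 0.

    Edge weight is −ln|c_ij|; an uncorrelated contact (c = 0) would have
    infinite weight and is simply omitted.
    """
    if not np.array_equal(cmap.residue_index, corr.residue_index):
        raise ValueError("contact map and correlation matrix cover "
                         "different residue lists")
    g = nx.Graph()
    labels = {}
    for k, node in enumerate(cmap.residue_index):
        g.add_node(int(node))
        labels[int(node)] = cmap.labels[k]
    n = cmap.n_residues
    for a in range(n):
        for b in range(a + 1, n):
            p = cmap.matrix[a, b]
            if p <= persistence:
                continue
            c = corr.matrix[a, b]
            if c == 0.0:
                continue
            w = float(-np.log(abs(c)))
            g.add_edge(int(cmap.residue_index[a]), int(cmap.residue_index[b]),
                       weight=max(w, 0.0), correlation=float(c),
                       probability=float(p))
    if g.number_of_edges() == 0:
        warnings.warn("dynamic network has no edges (degenerate ensemble?)")
    return WeightedNetwork(graph=g, labels=labels,
                           provenance={"persistence": persistence,
                                       "node_atom": corr.node_atom,
                                       "state": cmap.state})


def edge_betweenness(
    network: WeightedNetwork | nx.Graph, weighted: bool = True
) -> dict[tuple, float]:
    """Unnormalised edge betweenness; shortest-path ties split fractionally."""
    g = network.graph if isinstance(network, WeightedNetwork) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    bc = nx.edge_betweenness_centrality(
        g, normalized=False, weight="weight" if weighted else None)
    return {tuple(sorted(e)): v for e, v in bc.items()}
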