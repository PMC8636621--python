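"""Difference contact network analysis (dCNA) across functional states.

The pipeline: (1) per-state contact maps; (2) a consensus network whose
edges are contacts stable in every state; (3) divisive Girvan–Newman
community detection on the (unweighted) consensus network with a
modularity-convergence stop; (4) per-transition difference maps
d_ij = p_ij(to) − p_ij(from) summed over community pairs,

    ΔP_AB = Σ d_ij  for i ∈ A, j ∈ B (A ≠ B, unordered residue pairs),

so a positive ΔP_AB marks a net gain of contacts between communities A and
B along the transition and a negative value a net loss.  Over a closed
cycle of transitions the ΔP matrices telescope to zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .contacts import ContactMap

__all__ = [
    "ConsensusNetwork",
    "Partition",
    "TransitionDelta",
    "build_consensus_network",
    "modularity",
    "girvan_newman_partition",
    "difference_map",
    "community_delta",
    "hydrolysis_cycle_deltas",
]


@dataclass
class ConsensusNetwork:
    """Unweighted graph of contacts stable across all contributing states."""

    graph: nx.Graph
    residue_index: np.ndarray
    labels: list[str]
    threshold: float
    states: list[str]
    mode: str = "intersection"


@dataclass
class Partition:
    """Community assignment with its modularity and the divisive Q trace."""

    community_of: dict[int, int]
    n_communities: int
    modularity: float
    trace: list[float] = field(default_factory=list)

    def communities(self) -> list[list[int]]:
        out: dict[int, list[int]] = {}
        for node, cid in self.community_of.items():
            out.setdefault(cid, []).append(node)
        return [sorted(out[c]) for c in sorted(out)]

    def to_tsv(self, path: str, labels: dict[int, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("node\tlabel\tcommunity\n")
            for node in sorted(self.community_of):
                lab = (labels or {}).get(node, str(node))
                fh.write(f"{node}\t{lab}\t{self.community_of[node]}\n")

    def summary_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"n_communities": self.n_communities,
                       "modularity": self.modularity,
                       "trace": self.trace}, fh, indent=2)


@dataclass
class TransitionDelta:
    """Residue- and community-level contact-probability change for one transition."""

    label: str                       # e.g. "apo->ATP"
    residue_index: np.ndarray
    difference: np.ndarray           # (N, N) d_ij = p_to − p_from
    delta_p: np.ndarray              # (K, K) ΔP_AB, zero diagonal
    community_ids: list[int]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transition\t{self.label}\n")
            fh.write("communityA\tcommunityB\tdelta_p\n")
            k = len(self.community_ids)
            for a in range(k):
                for b in range(a + 1, k):
                    fh.write(f"{self.community_ids[a]}\t{self.community_ids[b]}"
                             f"\t{self.delta_p[a, b]:.6f}\n")


def _check_same_residues(maps: list[ContactMap]) -> None:
    ref = maps[0].residue_index
    for m in maps[1:]:
        if not np.array_equal(m.residue_index, ref):
            raise ValueError("contact maps cover different residue lists")


def build_consensus_network(
    maps: list[ContactMap],
    threshold: float = 0.90,
    mode: str = "intersection",
) -> ConsensusNetwork:
    """Consensus graph of contacts persistent across all functional states.

    ``intersection`` (default): edge iff p_ij ≥ threshold in every state.
    ``subtraction`` (alternative reading of the consensus construction):
    edge iff p_ij ≥ threshold in the first (reference) state and the
    contact probability changes by at most 1 − threshold in every other
    state.  Edge weights are all 1.0.
    """
    if len(maps) < 2:
        raise ValueError("consensus requires at least two states")
    _check_same_residues(maps)
    n = maps[0].n_residues
    stack = np.array([m.matrix for m in maps])
    if mode == "intersection":
        keep = np.all(stack >= threshold, axis=0)
    elif mode == "subtraction":
        ref = stack[0]
        stable = np.all(np.abs(stack[1:] - ref[None]) <= (1.0 - threshold), axis=0)
        keep = (ref >= threshold) & stable
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    g = nx.Graph()
    for k, node in enumerate(maps[0].residue_index):
        g.add_node(int(node))
    for i in range(n):
        for j in range(i + 1, n):
            if keep[i, j]:
                g.add_edge(int(maps[0].residue_index[i]),
                           int(maps[0].residue_index[j]), weight=1.0)
    return ConsensusNetwork(graph=g, residue_index=maps[0].residue_index,
                            labels=list(maps[0].labels), threshold=threshold,
                            states=[m.state for m in maps], mode=mode)


def modularity(graph: nx.Graph, communities) -> float:
    """Newman modularity Q = Σ_c [e_c/m − (d_c/2m)²] of an unweighted partition."""
    if isinstance(communities, Partition):
        communities = communities.communities()
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    seen = set()
    for comm in communities:
        cs = set(comm)
        seen |= cs
        e_c = sum(1 for u, v in graph.edges if u in cs and v in cs)
        d_c = sum(graph.degree(u) for u in cs)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    if seen != set(graph.nodes):
        raise ValueError("partition does not cover all nodes")
    return q


def _components_partition(graph: nx.Graph) -> list[set]:
    return sorted((set(c) for c in nx.connected_components(graph)),
                  key=lambda s: min(s))


def girvan_newman_partition(
    network: ConsensusNetwork | nx.Graph,
    modularity_tol: float = 0.001,
) -> Partition:
    """Divisive Girvan–Newman community detection with a modularity stop.

    Repeatedly removes the edge of maximal (unweighted, exact) edge
    betweenness, recomputing betweenness after every removal; each time the
    component structure changes, the induced partition's modularity is
    evaluated.  The subdivision stops once the modularity difference
    between successive accepted partitions drops below ``modularity_tol``,
    and the best-modularity partition seen up to that point is returned.
    Ties in betweenness are broken toward the lexicographically smallest
    edge for determinism.  A tolerance of −inf runs the full divisive
    trace (every edge removed).
    """
    base = network.graph if isinstance(network, ConsensusNetwork) else network
    if base.number_of_nodes() == 0:
        raise ValueError("empty network")
    work = nx.Graph()
    work.add_nodes_from(base.nodes)
    work.add_edges_from(base.edges)

    if work.number_of_edges() == 0:
        warnings.warn("edgeless network: every node is its own community")
        comm = {n: i for i, n in enumerate(sorted(work.nodes))}
        return Partition(community_of=comm, n_communities=len(comm),
                         modularity=0.0, trace=[0.0])

    def q_of(parts) -> float:
        return modularity(base, [sorted(p) for p in parts])

    parts = _components_partition(work)
    trace = [q_of(parts)]
    best_parts, best_q = parts, trace[0]
    prev_q = trace[0]
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, normalized=False, weight=None)
        target = min((e for e in bc), key=lambda e: (-bc[e], tuple(sorted(e))))
        work.remove_edge(*target)
        new_parts = _components_partition(work)
        if len(new_parts) == len(parts):
            continue
        parts = new_parts
        q = q_of(parts)
        trace.append(q)
        if q > best_q:
            best_q, best_parts = q, parts
        if q - prev_q < modularity_tol:
            break
        prev_q = q

    comm_sorted = sorted((sorted(p) for p in best_parts), key=lambda p: p[0])
    community_of = {n: cid for cid, comm in enumerate(comm_sorted) for n in comm}
    return Partition(community_of=community_of, n_communities=len(comm_sorted),
                     modularity=best_q, trace=trace)


def difference_map(map_to: ContactMap, map_from: ContactMap) -> np.ndarray:
    """d_ij = p_ij(to) − p_ij(from); symmetric, in [−1, 1]."""
    _check_same_residues([map_to, map_from])
    return map_to.matrix - map_from.matrix


def community_delta(
    diff: np.ndarray,
    partition: Partition,
    residue_index: np.ndarray,
) -> tuple[np.ndarray, list[int]]:
    """ΔP_AB = Σ_{i∈A, j∈B} d_ij over unordered cross-community residue pairs.

    Returns the symmetric (K, K) matrix (zero diagonal, by convention the
    within-community change is not reported) and the community id order.
    """
    ids = sorted(set(partition.community_of.values()))
    pos = {cid: k for k, cid in enumerate(ids)}
    n = diff.shape[0]
    comm = np.array([pos[partition.community_of[int(r)]] for r in residue_index])
    K = len(ids)
    out = np.zeros((K, K))
    for i in range(n):
        ci = comm[i]
        for j in range(i + 1, n):
            cj = comm[j]
            if ci == cj:
                continue
            d = diff[i, j]
            out[ci, cj] += d
            out[cj, ci] += d
    return out, ids


def hydrolysis_cycle_deltas(
    maps: dict[str, ContactMap],
    partition: Partition,
    cycle: tuple[str, str, str] = ("apo", "ATP", "ADP"),
) -> list[TransitionDelta]:
    """The three transition deltas of a closed hydrolysis cycle.

    For the default cycle the transitions are apo→ATP, ATP→ADP, ADP→apo;
    their ΔP matrices telescope to zero exactly.
    """
    missing = [s for s in cycle if s not in maps]
    if missing:
        raise ValueError(f"missing state(s): {missing}")
    _check_same_residues([maps[s] for s in cycle])
    out = []
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        d = difference_map(maps[b], maps[a])
        dp, ids = community_delta(d, partition, maps[a].residue_index)
        out.append(TransitionDelta(label=f"{a}->{b}",
                                   residue_index=maps[a].residue_index,
                                   difference=d, delta_p=dp,
                                   community_ids=ids))
    return out
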