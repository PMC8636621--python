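"""Synthetic multi-state ensembles and toy graphs with known ground truth.

The planted-ensemble generator emulates what the analysis pipeline needs
from a set of MD trajectories — several functional states of a
residue-resolved ensemble with (a) planted contact probabilities per
residue pair per state, (b) block-correlated positional fluctuations that
define planted communities, and (c) controlled inter-community contact
gains/losses that define a planted ΔP ground truth.  It makes no attempt
at force-field realism.

Geometry: each residue is a bead (node atom ``CA``) placed on a widely
spaced 3-D layout; every *designated* contact pair additionally owns a
dedicated pair of satellite atoms near the pair's midpoint whose
separation is toggled inside/outside the contact cutoff by an independent
Bernoulli draw each frame.  Because only the satellites move radially,
each pair's contact state is controlled independently and the node-atom
displacement field (which sets the correlations) is untouched.  Node
displacements are d_i(t) = √ρ·s_k(t) + √(1−ρ)·ε_i(t) with a
community-shared Gaussian s_k and independent ε, giving intra-community
correlation ρ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .networks import WeightedNetwork
from .structure import Ensemble, Structure

__all__ = [
    "PlantedConfig",
    "GroundTruth",
    "generate_planted_ensembles",
    "toy_graph_from_edges",
    "random_toy_graph",
    "random_connected_graph",
    "enumerate_simple_paths",
    "exhaustive_best_partition",
    "brute_force_edge_betweenness",
]

# default per-state contact probabilities of the designated inter-community
# pairs: contacts gained on nucleotide binding and partially retained after
# hydrolysis, all below typical consensus thresholds so the planted
# communities stay separable
_DEFAULT_INTER = {
    (0, 1): {"apo": 0.10, "ATP": 0.85, "ADP": 0.45},
    (0, 2): {"apo": 0.60, "ATP": 0.20, "ADP": 0.40},
    (1, 2): {"apo": 0.30, "ATP": 0.30, "ADP": 0.75},
}


@dataclass
class PlantedConfig:
    """Study conditions for the planted-community pseudo-ensembles."""

    n_communities: int = 3
    residues_per_community: int = 10
    states: tuple[str, ...] = ("apo", "ATP", "ADP")
    intra_contact_p: float = 0.95
    inter_contact_p: dict = field(default_factory=lambda: dict(_DEFAULT_INTER))
    n_inter_pairs: int = 3
    rho: float = 0.8                 # shared-motion correlation strength
    sigma: float = 0.5               # per-coordinate noise, Å
    n_frames: int = 1000
    seed: int = 0
    cutoff: float = 4.5
    contact_on_distance: float = 3.0
    contact_off_distance: float = 9.0

    def validate(self) -> None:
        if self.n_communities < 1 or self.residues_per_community < 2:
            raise ValueError("need ≥ 1 community of ≥ 2 residues")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        probs = [self.intra_contact_p] + [
            p for tab in self.inter_contact_p.values() for p in tab.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("contact probabilities must be in [0, 1]")
        if self.cutoff <= 0 or self.contact_on_distance > self.cutoff or \
                self.contact_off_distance <= self.cutoff:
            raise ValueError("need on-distance ≤ cutoff < off-distance")
        if self.n_inter_pairs > self.residues_per_community:
            raise ValueError("more inter pairs than residues per community")


@dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    partition: dict[int, int]                    # residue → community
    contact_p: dict[str, np.ndarray]             # state → (N, N) planted p
    delta_p: dict[str, np.ndarray]               # "a->b" → (K, K) implied ΔP
    rho: float
    designated_pairs: list[tuple[int, int]]

    def transitions(self) -> list[str]:
        return list(self.delta_p)


def _community_layout(n: int, min_base: float = 30.0,
                      min_mid: float = 14.0) -> np.ndarray:
    """Bead positions for one community, scaled so that bases are well
    separated and all pair midpoints are isolated from each other and from
    the bases (the satellite construction relies on this)."""
    from .metrics import sphere_points

    u = sphere_points(n)
    pairs = list(combinations(range(n), 2))
    mids = np.array([(u[i] + u[j]) / 2.0 for i, j in pairs])
    d_base = min(np.linalg.norm(u[i] - u[j]) for i, j in pairs)
    d_mid = min(np.linalg.norm(a - b)
                for a, b in combinations(mids, 2)) if len(mids) > 1 else 1.0
    d_bm = min(np.linalg.norm(u[i] - mids[k])
               for k, (a, b) in enumerate(pairs)
               for i in range(n) if i not in (a, b)) if n > 2 else 1.0
    if min(d_base, d_mid, d_bm) < 1e-6:
        raise ValueError("degenerate community layout; too many beads")
    scale = max(min_base / d_base, min_mid / d_mid, min_mid / d_bm)
    return u * scale


def generate_planted_ensembles(config: PlantedConfig):
    """One Ensemble per state plus the planted ground truth.

    Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, npc = config.n_communities, config.residues_per_community
    N = K * npc
    layout = _community_layout(npc)
    extent = np.abs(layout).max()
    spacing = max(8.0 * extent, 300.0)
    centers = np.zeros((K, 3))
    for k in range(K):  # widely separated community centres on a helix
        ang = 2.0 * np.pi * k / max(K, 2)
        centers[k] = [spacing * np.cos(ang), spacing * np.sin(ang),
                      0.6 * spacing * k]
    base = np.concatenate([centers[k] + layout for k in range(K)])

    # designated pairs: all intra-community pairs + matched inter pairs
    intra_pairs = [(k * npc + i, k * npc + j)
                   for k in range(K) for i, j in combinations(range(npc), 2)]
    inter_pairs, inter_tab = [], []
    for (a, b), table in sorted(config.inter_contact_p.items()):
        if a >= K or b >= K:
            continue
        for q in range(config.n_inter_pairs):
            inter_pairs.append((a * npc + q, b * npc + q))
            inter_tab.append(table)
    designated = intra_pairs + inter_pairs

    # topology: one CA bead per residue + two satellites per designated
    # pair, laid out residue-contiguously so PDB round trips preserve order
    pairs_of: dict[int, list[int]] = {r: [] for r in range(N)}
    for npair, (i, j) in enumerate(designated):
        pairs_of[i].append(npair)
        pairs_of[j].append(npair)
    atom_name: list[str] = []
    atom_res: list[int] = []
    core_idx = np.empty(N, dtype=int)
    sat_slice = [[-1, -1] for _ in designated]
    for r in range(N):
        core_idx[r] = len(atom_name)
        atom_name.append("CA")
        atom_res.append(r)
        for npair in pairs_of[r]:
            side = 0 if designated[npair][0] == r else 1
            sat_slice[npair][side] = len(atom_name)
            atom_name.append(f"S{npair}{'A' if side == 0 else 'B'}")
            atom_res.append(r)
    A = len(atom_name)
    resseq = np.tile(1 + 2 * np.arange(npc), K)    # 1,3,5,… avoids the
    chain = np.repeat([chr(ord("A") + k) for k in range(K)], npc)  # bonded filter
    topology = Structure(
        atom_name=np.array(atom_name), element=np.array(["C"] * A),
        coords=np.zeros((A, 3)), occupancy=np.ones(A), bfactor=np.zeros(A),
        atom_resindex=np.array(atom_res, dtype=int),
        chain_id=chain, resseq=resseq, icode=np.array([""] * N),
        resname=np.array(["ALA"] * N), polymer=np.array(["protein"] * N),
    )

    mids = np.array([(base[i] + base[j]) / 2.0 for i, j in designated])
    units = np.array([(base[j] - base[i]) for i, j in designated])
    units /= np.linalg.norm(units, axis=1, keepdims=True)

    # planted probabilities
    p_planted = {s: np.zeros((N, N)) for s in config.states}
    for s in config.states:
        for i, j in intra_pairs:
            p_planted[s][i, j] = p_planted[s][j, i] = config.intra_contact_p
        for (i, j), tab in zip(inter_pairs, inter_tab):
            p = tab.get(s, 0.0)
            p_planted[s][i, j] = p_planted[s][j, i] = p

    comm_of = {r: r // npc for r in range(N)}
    delta_gt: dict[str, np.ndarray] = {}
    states = list(config.states)
    for a, b in zip(states, states[1:] + states[:1]):
        dp = np.zeros((K, K))
        for (i, j), tab in zip(inter_pairs, inter_tab):
            d = tab.get(b, 0.0) - tab.get(a, 0.0)
            ca, cb = comm_of[i], comm_of[j]
            dp[ca, cb] += d
            dp[cb, ca] += d
        delta_gt[f"{a}->{b}"] = dp

    ensembles = {}
    T = config.n_frames
    sq_rho, sq_eps = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    for s in config.states:
        shared = rng.normal(0.0, config.sigma, size=(T, K, 3))
        indiv = rng.normal(0.0, config.sigma, size=(T, N, 3))
        disp = sq_rho * shared[:, [comm_of[r] for r in range(N)], :] \
            + sq_eps * indiv
        frames = np.empty((T, A, 3))
        frames[:, core_idx, :] = base[None] + disp
        probs = np.array([p_planted[s][i, j] for i, j in designated])
        on = rng.random(size=(T, len(designated))) < probs[None, :]
        half = np.where(on, config.contact_on_distance,
                        config.contact_off_distance) / 2.0
        for npair, (ai, aj) in enumerate(sat_slice):
            offset = units[npair][None, :] * half[:, npair, None]
            frames[:, ai, :] = mids[npair][None, :] - offset
            frames[:, aj, :] = mids[npair][None, :] + offset
        ensembles[s] = Ensemble(topology=topology, frames=frames, state=s)

    truth = GroundTruth(partition=comm_of, contact_p=p_planted,
                        delta_p=delta_gt, rho=config.rho,
                        designated_pairs=designated)
    return ensembles, truth


# ---------------------------------------------------------------------------
# toy graphs with exhaustive oracles
# ---------------------------------------------------------------------------

def toy_graph_from_edges(edges) -> WeightedNetwork:
    """WeightedNetwork from (u, v, weight) triples; weights must be ≥ 0."""
    g = nx.Graph()
    for u, v, w in edges:
        if w < 0:
            raise ValueError("edge weights must be nonnegative")
        g.add_edge(u, v, weight=float(w))
    return WeightedNetwork(graph=g, labels={n: str(n) for n in g.nodes},
                           provenance={"source": "toy"})


def random_toy_graph(n: int, edge_prob: float, seed: int,
                     max_weight: float = 5.0) -> WeightedNetwork:
    """Seeded Erdős–Rényi graph with uniform random nonnegative weights."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, max_weight)))
    return WeightedNetwork(graph=g, labels={v: str(v) for v in g.nodes},
                           provenance={"source": "random", "seed": seed})


def random_connected_graph(n: int, edge_prob: float, seed: int,
                           max_weight: float = 5.0) -> WeightedNetwork:
    """Like :func:`random_toy_graph` but resampled until connected."""
    for attempt in range(1000):
        net = random_toy_graph(n, edge_prob, seed * 1009 + attempt, max_weight)
        if net.n_nodes == n and nx.is_connected(net.graph):
            return net
    raise RuntimeError("could not sample a connected graph")


def enumerate_simple_paths(graph: nx.Graph, source, target,
                           ) -> list[tuple[float, tuple]]:
    """All simple source→target paths, sorted by (total weight, sequence)."""
    out = []
    for p in nx.all_simple_paths(graph, source, target):
        w = sum(graph[u][v]["weight"] for u, v in zip(p, p[1:]))
        out.append((float(w), tuple(p)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _set_partitions(items: list):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


def exhaustive_best_partition(graph: nx.Graph):
    """Globally modularity-optimal partition by exhaustive enumeration.

    Exponential (Bell-number) cost; intended for graphs with ≤ 10 nodes.
    """
    from .dcna import modularity

    nodes = sorted(graph.nodes)
    if len(nodes) > 12:
        raise ValueError("exhaustive search limited to ≤ 12 nodes")
    best_q, best = -np.inf, None
    for parts in _set_partitions(nodes):
        q = modularity(graph, parts)
        if q > best_q + 1e-15:
            best_q, best = q, [sorted(p) for p in parts]
    return best, float(best_q)


def brute_force_edge_betweenness(graph: nx.Graph,
                                 weighted: bool = True) -> dict:
    """Edge betweenness by enumerating all-pairs minimum-weight simple paths;
    ties split fractionally.  Exponential; for ≤ 12-node graphs."""
    bc = {tuple(sorted(e)): 0.0 for e in graph.edges}
    nodes = sorted(graph.nodes)
    for a, b in combinations(nodes, 2):
        paths = []
        for p in nx.all_simple_paths(graph, a, b):
            w = sum(graph[u][v]["weight"] if weighted else 1.0
                    for u, v in zip(p, p[1:]))
            paths.append((w, p))
        if not paths:
            continue
        wmin = min(w for w, _ in paths)
        minimal = [p for w, p in paths if abs(w - wmin) <= 1e-12]
        share = 1.0 / len(minimal)
        for p in minimal:
            for u, v in zip(p, p[1:]):
                bc[tuple(sorted((u, v)))] += share
    return bc
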