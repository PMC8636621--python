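# Methods

This note records the models implemented in `dyncon`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Contact probabilities

A residue pair (i, j) is *in contact* in a frame when the minimum distance
between their heavy atoms is ≤ the cutoff (default **4.5 Å**, the common
heavy-atom contact criterion for dynamic-network construction; the
boundary is inclusive). The contact probability `p_ij` is the fraction of
frames in contact, so `p_ij·T` is always an integer count. Hydrogens are
retained in the data model but excluded from contact geometry.

Sequence neighbours (|residue-number difference| ≤ 1 within one chain,
configurable) are zeroed: covalently bonded residues are trivially in
contact in every frame and would otherwise dominate every network.
Non-polymer residues (ions, small ligands) are excluded from the node set
by default; nucleotide ligands can be opted in through a selection.

*Persistent* contacts are those with `p_ij` **strictly greater** than the
persistence threshold (0.5 for contact tables, 0.75 for path networks), so
a pair sitting exactly at the threshold is excluded.

### Chemical classification

The geometric class criteria are declared package defaults (standard
literature values), not a reproduction of any particular study's unstated
settings, and all are overridable:

| class | criterion | default |
|---|---|---|
| salt bridge | Lys/Arg/His side-chain N … Asp/Glu side-chain O or nucleic phosphate O | ≤ 4.0 Å |
| hydrogen bond | donor heavy atom … acceptor (D–H…A ≥ 120° when H present) | ≤ 3.5 Å |
| hydrophobic | apolar side-chain C … apolar side-chain C | ≤ 4.5 Å |

Each criterion is evaluated per frame; the reported class is the one with
the highest persistence fraction, ties resolved toward the most specific
class (salt-bridge > hydrogen-bond > hydrophobic, since salt-bridge
geometry implies hydrogen-bond geometry). If no class exceeds the
persistence threshold the contact is "other". Nonstandard residues fall
back to generic element-based typing (N → donor/cation, O →
acceptor/anion, C → apolar) with a warning.

## Correlation-weighted networks

Node positions are Cα for amino acids and P for nucleotides (the same
atoms used for RMSD bookkeeping of mixed protein–nucleic complexes); a
heavy-atom-centroid convention is available. The cross-correlation

    c_ij = ⟨Δr_i · Δr_j⟩ / (⟨|Δr_i|²⟩^½ ⟨|Δr_j|²⟩^½),  Δr = r − ⟨r⟩

uses averages over frames. Edges join residue pairs with `p_ij > 0.75`
and carry weight `w_ij = −ln |c_ij|`; a contact with `c_ij = 0` would have
infinite weight and is omitted — an uncorrelated contact carries no
communication in this metric. Residues with zero positional fluctuation
have undefined correlations, reported as 0 with a warning; a fully rigid
ensemble therefore yields an edgeless network, not a crash.

**Superposition.** By default every frame is least-squares fitted onto the
ensemble mean of the node atoms (two iterations, the mean being recomputed
after each pass) so that rigid-body drift is not mistaken for internal
correlation. This fit necessarily removes the net mean displacement of
each frame; when a system consists of only a few large quasi-rigid blocks,
that subtraction converts genuinely shared block motion into apparent
anticorrelation between blocks. For real trajectories, with thousands of
residues and drift that must be removed, the fit is the right default.
The synthetic generator, by contrast, emits ensembles in a fixed
laboratory frame with no drift at all, so recovery measurements on
generated data disable the fit (`superpose_iterations=0`); with it
enabled, the planted block correlation would be systematically distorted
by the mean-removal artifact rather than by any property of the estimator
under test.

## Consensus network and communities

The consensus network across functional states has an (unweighted,
weight-1.0) edge wherever `p_ij ≥ 0.9` **in every state** — a contact
persistent across the whole cycle. The threshold comparison is inclusive.
An alternative "subtraction" mode is provided (edge iff the contact passes
the threshold in a reference state and its probability changes by at most
1 − threshold in every other state); the intersection rule is the default
because it directly expresses "stable across all simulations".

Communities are found by divisive Girvan–Newman partitioning: repeatedly
remove the edge of maximal edge betweenness (exact, recomputed after every
removal, unweighted — community structure is a property of the contact
topology, not of the correlation weights), and each time the component
structure changes evaluate Newman modularity

    Q = Σ_c [ e_c/m − (d_c/2m)² ]

of the induced partition **on the original graph**. Subdivision stops once
the modularity difference between successive accepted partitions falls
below the tolerance (default **0.001**), and the best-Q partition seen is
returned. Ties in betweenness are broken toward the lexicographically
smallest edge, making the procedure fully deterministic. Edgeless input
returns singleton communities with Q = 0 and a warning; disconnected
components can never merge.

ΔP sums run over **unordered** residue pairs, each cross-community pair
counted once; the ΔP matrix is symmetric and its diagonal (within-
community change) is not reported. Antisymmetry under transition reversal
and exact telescoping over a closed three-state cycle follow algebraically
and are enforced by tests to 10⁻¹².

## Optimal and suboptimal paths

Edge weights are nonnegative, so Dijkstra gives the optimal path weight;
among equal-weight optimal paths (possible when |c| = 1 gives zero-weight
edges) the lexicographically smallest node sequence is returned, found by
a depth-first search over the optimality subgraph with backtracking.
Suboptimal enumeration follows the SOAN recipe: reduce the graph to nodes
within `hop_radius` (default **2**) unweighted hops of any optimal-path
node, then enumerate the `k` (default **5000**) lowest-weight simple paths
in the reduced graph with deviation-based (Yen) enumeration. The tie group
straddling the k-th weight is collected in full and sorted by
(weight, node sequence) before truncation, so output is deterministic.
The reduction is an explicit trade-off: a low-weight detour through a node
farther than the hop radius from the optimal path is absent from the
output by construction (a test constructs exactly this case). With hop
radius ≥ graph diameter the enumeration is provably exhaustive, which is
how the oracle tests validate it.

Path-composition statistics count, for every node, the number of returned
paths containing it; a query set's "on-path fraction" is the fraction of
its members on ≥ 1 path (optionally widened to 1-hop network neighbours of
path nodes). Networks are undirected, so swapping source and target does
not change the path set.

## Structural metrics

- **SASA** — Shrake–Rupley with Bondi van der Waals radii, probe radius
  1.4 Å (water), and 960 quasi-uniform golden-spiral sphere points per
  atom by default (isolated-sphere error < 1%, checked at 240/960/3840
  points). Unknown elements get a configurable 1.7 Å default with a
  warning.
- **BSA** — reported *unhalved*: BSA(A,B) = SASA(A) + SASA(B) − SASA(A∪B),
  i.e. the total area buried on both sides; `halved=True` gives the
  per-side convention. A subgroup S ⊆ A contributes BSA(S, B) — the same
  formula with S isolated against the full partner group — which makes the
  "subgroup = all of A" case reduce exactly to the total. Because
  isolating S also releases area that other A atoms occluded, percentages
  of disjoint subgroups are not guaranteed to sum to exactly 100%.
- **Ensemble B-factors** — `B_i = (8π²/3)·⟨|Δr_i|²⟩` of the node atom
  after the same superposition policy as the correlations; recovers
  `8π²σ²` within 5% for isotropic Gaussian fluctuation at T = 10⁴.
- **Duplex rotation** — frame b is superposed onto frame a on an anchoring
  selection; the optimal rotation carrying the duplex atoms of a onto b is
  extracted by Kabsch SVD and its angle read from the matrix trace (axis
  also reported). Selections with < 3 non-collinear atoms are rejected.
- **Map–model CCC** — a model density is simulated as atom-centred
  Gaussians with σ = 0.225·resolution (the common `molmap` convention;
  configurable) and amplitude proportional to atomic number, on the
  experimental grid; the Pearson correlation is evaluated over voxels
  where the simulated density exceeds 1% of its maximum (whole-box CCC is
  dominated by empty solvent; an all-voxel mode is available). CCC is
  invariant under affine rescaling of either map; a flat experimental
  region inside the model envelope returns CCC = 0.

## The synthetic generator

The generator emulates exactly the features of multi-state MD output the
pipeline consumes, with every planted quantity known in closed form:

- one bead residue per node (Cα), placed on a widely spaced layout in
  which communities are separate clusters;
- each *designated* contact pair owns a dedicated pair of satellite atoms
  near the pair's midpoint, toggled inside (3.0 Å) or outside (9.0 Å) the
  4.5 Å cutoff by an independent Bernoulli draw per frame — so measured
  `p̂_ij` is exactly binomial around the planted probability, and toggling
  one pair cannot create or destroy any other contact (the layout enforces
  ≥ 14 Å between distinct pair midpoints);
- node displacements `d_i(t) = √ρ·s_k(t) + √(1−ρ)·ε_i(t)` with a
  community-shared Gaussian `s_k` and independent `ε_i` (per-coordinate
  σ = 0.5 Å), giving intra-community correlation exactly ρ and
  inter-community correlation 0; satellites follow the static layout, so
  contact toggling leaves the displacement field untouched;
- identical seeds give bit-identical ensembles.

Default study conditions: 3 communities × 10 residues, states
(apo, ATP, ADP), T = 1000 frames, ρ = 0.8, intra-community contact
probability 0.95 in every state, and 3 designated inter-community pairs
per community pair whose probabilities encode a gain-on-binding /
partial-retention-on-hydrolysis cycle (e.g. 0.10 → 0.85 → 0.45 between
communities 0 and 1), all kept below the 0.9 consensus threshold so the
planted communities remain separable. The implied ΔP ground truth
telescopes to zero by construction.

What the generator does **not** emulate: force-field physics, side-chain
packing, time-correlated (non-i.i.d.) contact dynamics, rigid-body drift,
solvent, or the geometry of any real complex. Passing the recovery tests
therefore demonstrates correctness of the estimators and graph algorithms
under the stated statistical model — not that any particular biological
conclusion would be recovered from real trajectories.

## Problem sizes and tolerances in the validation suite

All sizes are package choices balancing statistical power against an
ordinary workstation run:

- cycle closure: 12-residue random three-state maps, closure to 10⁻¹²;
- Girvan–Newman oracle: 50 random connected graphs of 5–9 nodes (sizes at
  which exhaustive Bell-number partition search is the oracle), compared
  wherever the exhaustive optimum is reachable by divisive edge removal;
  barbell(4,4) must give K = 2, Q = 12/13 − 1/2;
- SOAN oracle: 100 random connected weighted graphs of 5–10 nodes with
  hop radius set to the graph diameter, exact list equality against
  brute-force enumeration;
- planted recovery: 50 generator seeds at the default study conditions;
  exact partition recovery in ≥ 95% of seeds, ΔP within 3σ binomial
  bounds, intra-community |c| ≥ 0.7 (expected value ρ = 0.8);
- analytic metrics: isolated-sphere SASA within 1%, two-sphere BSA within
  2% of the spherical-cap closed form, B-factor within 5% at T = 10⁴,
  constructed 14° rotation within 10⁻⁶ degrees.

## Known limitations

- Contact counting treats frames as exchangeable; no statistical-
  inefficiency correction for autocorrelated trajectories is applied.
- Girvan–Newman recomputes exact betweenness after every edge removal:
  O(VE) per removal, fine up to a few thousand nodes but not beyond.
- The k-shortest-path enumerator materialises the tie group around the
  k-th path; graphs with massive zero-weight degeneracy can make that
  group large.
- mmCIF writing covers coordinates and identities only (no assemblies,
  anisotropic factors, or entity metadata beyond what gemmi derives).
- Density handling assumes orthogonal map cells and axis-aligned grids.
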