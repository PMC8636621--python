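"""Residue–residue contact probabilities over an ensemble.

A residue pair is "in contact" in a frame when any two of its heavy atoms
are within the distance cutoff (4.5 Å by default).  Contact probability is
the fraction of frames in contact; persistent contacts are those above a
persistence threshold (strictly greater, so p = threshold is excluded).
Sequence-adjacent residues in the same chain are excluded by default so
that covalently bonded neighbours do not dominate the networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .selections import Selection, select_residues
from .structure import Ensemble, Structure, StructureError

__all__ = [
    "ContactMap",
    "ContactCriteria",
    "residue_contact_frame",
    "compute_contact_map",
    "persistent_contacts",
    "classify_contact",
]

DEFAULT_CUTOFF = 4.5  # Å, heavy-atom minimum distance


@dataclass
class ContactMap:
    """Symmetric residue×residue contact-probability matrix for one state."""

    state: str
    residue_index: np.ndarray       # (N,) global residue indices in the topology
    labels: list[str]               # residue labels "chain:resseq"
    matrix: np.ndarray              # (N, N) probabilities, zero diagonal
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.residue_index),) * 2:
            raise ValueError("matrix shape does not match residue list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    def to_tsv(self, path: str) -> None:
        """Write nonzero upper-triangle entries plus a commented header."""
        with open(path, "w") as fh:
            fh.write(f"# state\t{self.state}\n")
            fh.write(f"# cutoff\t{self.cutoff}\n")
            fh.write(f"# n_frames\t{self.n_frames}\n")
            fh.write("# residues\t" + ",".join(
                f"{idx}={lab}" for idx, lab in
                zip(self.residue_index, self.labels)) + "\n")
            fh.write("chainA\tresidA\tchainB\tresidB\tprobability\n")
            n = self.n_residues
            for i in range(n):
                ca, ra = self.labels[i].split(":")
                for j in range(i + 1, n):
                    p = self.matrix[i, j]
                    if p > 0:
                        cb, rb = self.labels[j].split(":")
                        fh.write(f"{ca}\t{ra}\t{cb}\t{rb}\t{p:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ContactMap":
        state, cutoff, n_frames = "", DEFAULT_CUTOFF, 0
        residue_index: list[int] = []
        labels: list[str] = []
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("\t")
                    if key == "state":
                        state = val
                    elif key == "cutoff":
                        cutoff = float(val)
                    elif key == "n_frames":
                        n_frames = int(val)
                    elif key == "residues":
                        for item in val.split(","):
                            idx, _, lab = item.partition("=")
                            residue_index.append(int(idx))
                            labels.append(lab)
                elif line and not line.startswith("chainA"):
                    rows.append(line.split("\t"))
        pos = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))
        for ca, ra, cb, rb, p in rows:
            i, j = pos[f"{ca}:{ra}"], pos[f"{cb}:{rb}"]
            mat[i, j] = mat[j, i] = float(p)
        return cls(state=state, residue_index=np.array(residue_index, dtype=int),
                   labels=labels, matrix=mat, cutoff=cutoff, n_frames=n_frames)


def _heavy_atoms_of(structure: Structure, residues: np.ndarray):
    """Heavy-atom indices and their residue mapping, restricted to a scope."""
    heavy = structure.heavy_mask()
    in_scope = structure.residue_atom_mask(residues)
    idx = np.nonzero(heavy & in_scope)[0]
    return idx, structure.atom_resindex[idx]


def residue_contact_frame(
    structure: Structure,
    i: int,
    j: int,
    cutoff: float = DEFAULT_CUTOFF,
    coords: np.ndarray | None = None,
) -> bool:
    """True iff the minimum heavy-atom distance between residues i, j ≤ cutoff."""
    if i == j:
        raise ValueError("contact requires two distinct residues")
    xyz = structure.coords if coords is None else coords
    heavy = structure.heavy_mask()
    ai = structure.residue_atom_indices(i)
    aj = structure.residue_atom_indices(j)
    ai, aj = ai[heavy[ai]], aj[heavy[aj]]
    if len(ai) == 0 or len(aj) == 0:
        raise StructureError("residue with no heavy atoms")
    d = np.linalg.norm(xyz[ai][:, None, :] - xyz[aj][None, :, :], axis=-1)
    return bool(d.min() <= cutoff)


def _adjacent_pairs_mask(structure: Structure, residues: np.ndarray,
                         bond_gap: int) -> np.ndarray:
    """(N, N) True where |resseq difference| ≤ bond_gap within one chain."""
    n = len(residues)
    chain = structure.chain_id[residues]
    seq = structure.resseq[residues]
    same_chain = chain[:, None] == chain[None, :]
    close = np.abs(seq[:, None] - seq[None, :]) <= bond_gap
    return same_chain & close


def compute_contact_map(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_CUTOFF,
    residue_scope: Selection | str | None = None,
    exclude_bonded: int = 1,
) -> ContactMap:
    """Contact probabilities p_ij over all frames of an ensemble.

    Non-polymer residues are excluded unless explicitly selected;
    ``exclude_bonded`` zeroes pairs within that residue-number distance in
    the same chain (1 = direct sequence neighbours).
    """
    top = ensemble.topology
    if residue_scope is None:
        residues = np.nonzero(top.polymer != "other")[0]
    else:
        residues = np.array(sorted(select_residues(top, residue_scope)), dtype=int)
    if len(residues) == 0:
        raise ValueError("empty residue scope")
    n = len(residues)
    pos = {int(r): k for k, r in enumerate(residues)}
    atom_idx, atom_res = _heavy_atoms_of(top, residues)
    if len(atom_idx) == 0:
        raise StructureError("no heavy atoms in scope")
    atom_local = np.array([pos[int(r)] for r in atom_res], dtype=int)

    counts = np.zeros((n, n), dtype=np.int64)
    for t in range(ensemble.n_frames):
        xyz = ensemble.frames[t][atom_idx]
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ri = atom_local[pairs[:, 0]]
        rj = atom_local[pairs[:, 1]]
        keep = ri != rj
        ri, rj = ri[keep], rj[keep]
        lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
        flat = np.unique(lo * n + hi)
        counts.flat[flat] += 1

    mat = counts / float(ensemble.n_frames)
    mat = mat + mat.T
    np.fill_diagonal(mat, 0.0)
    if exclude_bonded >= 0:
        adj = _adjacent_pairs_mask(top, residues, exclude_bonded)
        mat[adj] = 0.0
    labels = [top.residue_label(int(r)) for r in residues]
    return ContactMap(state=ensemble.state, residue_index=residues,
                      labels=labels, matrix=mat, cutoff=cutoff,
                      n_frames=ensemble.n_frames)


def persistent_contacts(
    cmap: ContactMap, threshold: float = 0.5
) -> list[tuple[int, int, float]]:
    """Pairs with p strictly above the persistence threshold.

    Returned as (i, j, p) with i < j in the map's local indexing, sorted by
    descending probability and then by (i, j).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    n = cmap.n_residues
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            p = cmap.matrix[i, j]
            if p > threshold:
                out.append((i, j, float(p)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# chemical classification of contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactCriteria:
    """Geometric criteria for chemical contact classes (Å / degrees).

    These are declared literature-standard defaults, not a reproduction of
    any particular study's unstated values.
    """

    salt_bridge: float = 4.0     # cationic N … anionic O
    hydrogen_bond: float = 3.5   # donor heavy atom … acceptor
    hydrophobic: float = 4.5     # apolar carbon … apolar carbon
    hbond_angle: float = 120.0   # D–H…A, applied only when H present


_CATION_ATOMS = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_ANION_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_PHOSPHATE_O = {"OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

_DONOR_ATOMS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
# polar carbons excluded from the hydrophobic class
_POLAR_CARBONS = {
    "ARG": {"CZ"}, "ASN": {"CG"}, "ASP": {"CG"}, "GLN": {"CD"},
    "GLU": {"CD"}, "TYR": {"CZ"},
}


def _atom_roles(structure: Structure, a: int) -> set[str]:
    """Roles for one atom: subsets of {cation, anion, donor, acceptor, apolar}."""
    ri = structure.atom_resindex[a]
    res = str(structure.resname[ri]).upper()
    name = str(structure.atom_name[a]).upper()
    el = str(structure.element[a]).upper()
    pol = structure.polymer[ri]
    roles: set[str] = set()
    standard = pol in ("protein", "nucleic") and (
        res in _AMINO_STANDARD or pol == "nucleic")
    if standard:
        if name in _CATION_ATOMS.get(res, ()):
            roles |= {"cation", "donor"}
        if name in _ANION_ATOMS.get(res, ()) or (
                pol == "nucleic" and name in _PHOSPHATE_O):
            roles |= {"anion", "acceptor"}
        if name == "N" and res != "PRO":
            roles.add("donor")
        if name in ("O", "OXT"):
            roles.add("acceptor")
        if name in _DONOR_ATOMS.get(res, ()):
            roles.add("donor")
        if name in _ACCEPTOR_ATOMS.get(res, ()):
            roles.add("acceptor")
        if pol == "nucleic":
            if el == "N":
                roles.add("donor")
            if el in ("N", "O"):
                roles.add("acceptor")
        if el == "C" and name not in ("C", "CA") and \
                name not in _POLAR_CARBONS.get(res, ()):
            roles.add("apolar")
    else:
        # generic typing for nonstandard residues
        if el == "N":
            roles |= {"donor", "cation"}
        if el == "O":
            roles |= {"acceptor", "anion"}
        if el == "S":
            roles |= {"donor", "acceptor"}
        if el == "C":
            roles.add("apolar")
    return roles


_AMINO_STANDARD = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _hydrogens_bonded_to(structure: Structure, xyz: np.ndarray, a: int) -> np.ndarray:
    """Hydrogens within covalent range (1.3 Å) of heavy atom ``a``."""
    ri = structure.atom_resindex[a]
    idx = structure.residue_atom_indices(ri)
    hyd = idx[np.char.upper(structure.element[idx].astype(str)) == "H"]
    if len(hyd) == 0:
        return hyd
    d = np.linalg.norm(xyz[hyd] - xyz[a], axis=1)
    return hyd[d <= 1.3]


@dataclass
class ContactClassification:
    """Dominant chemical class of a residue–residue contact."""

    contact_class: str                 # hydrogen-bond | salt-bridge | hydrophobic | other
    fractions: dict[str, float]        # per-class persistence fractions


def classify_contact(
    ensemble: Ensemble,
    i: int,
    j: int,
    criteria: ContactCriteria = ContactCriteria(),
    persistence_threshold: float = 0.5,
) -> ContactClassification:
    """Classify contact (i, j) as hydrogen-bond, salt-bridge or hydrophobic.

    Each class's geometric criterion is evaluated in every frame; the
    reported class is the one with the highest persistence fraction among
    those exceeding the persistence threshold.  Ties go to the most
    specific class (salt-bridge > hydrogen-bond > hydrophobic), since a
    salt bridge also satisfies hydrogen-bond geometry.  Nonstandard
    residues fall back to generic element-based typing with a warning.
    """
    top = ensemble.topology
    for r in (i, j):
        if top.polymer[r] == "other":
            warnings.warn(
                f"residue {top.residue_label(r)} is nonstandard; "
                "using generic donor/acceptor/apolar typing")
    heavy = top.heavy_mask()
    ai = top.residue_atom_indices(i)
    aj = top.residue_atom_indices(j)
    ai, aj = ai[heavy[ai]], aj[heavy[aj]]
    roles_i = [_atom_roles(top, a) for a in ai]
    roles_j = [_atom_roles(top, a) for a in aj]
    has_h = bool((~heavy).sum())

    def _pairs(role_a: str, role_b: str):
        out = []
        for a, ra in zip(ai, roles_i):
            for b, rb in zip(aj, roles_j):
                if (role_a in ra and role_b in rb) or \
                        (role_b in ra and role_a in rb):
                    out.append((a, b))
        return out

    salt_pairs = _pairs("cation", "anion")
    hb_pairs = _pairs("donor", "acceptor")
    apolar_pairs = _pairs("apolar", "apolar")

    counts = {"salt-bridge": 0, "hydrogen-bond": 0, "hydrophobic": 0}
    T = ensemble.n_frames
    for t in range(T):
        xyz = ensemble.frames[t]
        if any(np.linalg.norm(xyz[a] - xyz[b]) <= criteria.salt_bridge
               for a, b in salt_pairs):
            counts["salt-bridge"] += 1
        hb = False
        for a, b in hb_pairs:
            # orient donor→acceptor: the donor side is whichever has "donor"
            d = np.linalg.norm(xyz[a] - xyz[b])
            if d > criteria.hydrogen_bond:
                continue
            if not has_h:
                hb = True
                break
            donor = a if "donor" in _atom_roles(top, a) else b
            acceptor = b if donor == a else a
            hyds = _hydrogens_bonded_to(top, xyz, donor)
            if len(hyds) == 0:
                hb = True
                break
            for h in hyds:
                v1 = xyz[donor] - xyz[h]
                v2 = xyz[acceptor] - xyz[h]
                cosang = float(np.dot(v1, v2) /
                               (np.linalg.norm(v1) * np.linalg.norm(v2)))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang >= criteria.hbond_angle:
                    hb = True
                    break
            if hb:
                break
        if hb:
            counts["hydrogen-bond"] += 1
        if any(np.linalg.norm(xyz[a] - xyz[b]) <= criteria.hydrophobic
               for a, b in apolar_pairs):
            counts["hydrophobic"] += 1

    fractions = {k: v / T for k, v in counts.items()}
    precedence = ["salt-bridge", "hydrogen-bond", "hydrophobic"]
    best = max(precedence, key=lambda k: (fractions[k], -precedence.index(k)))
    if fractions[best] <= persistence_threshold:
        return ContactClassification("other", fractions)
    return ContactClassification(best, fractions)
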