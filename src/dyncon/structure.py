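"""Residue-centric structure and ensemble containers.

Structures are stored as flat numpy arrays (one row per atom) plus a residue
table; residues keep their author-assigned numbering (chain id, residue
number, insertion code) verbatim, while all internal indexing is 0-based.
Parsing of PDB/mmCIF goes through gemmi; binary trajectories (DCD/XTC) are
read with MDAnalysis and always stored in Å.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Structure",
    "Ensemble",
    "StructureError",
    "load_structure",
    "load_ensemble",
    "write_multimodel_pdb",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


# Minimal polymer classification; gemmi's residue-info table is consulted
# first, these sets are the fallback for nonstandard names.
_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_NUCLEIC = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}


def classify_residue(resname: str) -> str:
    """Return 'protein', 'nucleic' or 'other' for a residue name."""
    name = resname.strip().upper()
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "protein"
        if info.is_nucleic_acid():
            return "nucleic"
    if name in _AMINO:
        return "protein"
    if name in _NUCLEIC:
        return "nucleic"
    return "other"


@dataclass
class Structure:
    """A single conformer, organised chain → residue → atom.

    Atom arrays all have length ``n_atoms``; residue arrays have length
    ``n_residues``.  ``atom_resindex`` maps each atom to its residue row.
    """

    atom_name: np.ndarray          # (A,) str
    element: np.ndarray            # (A,) str, e.g. "C", "N", "H"
    coords: np.ndarray             # (A, 3) float, Å
    occupancy: np.ndarray          # (A,) float
    bfactor: np.ndarray            # (A,) float
    atom_resindex: np.ndarray      # (A,) int
    chain_id: np.ndarray           # (R,) str
    resseq: np.ndarray             # (R,) int, author numbering
    icode: np.ndarray              # (R,) str
    resname: np.ndarray            # (R,) str
    polymer: np.ndarray            # (R,) str in {protein, nucleic, other}

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        ids = list(zip(self.chain_id, self.resseq, self.icode))
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate residue identity (chain, number, icode)")

    # -- basic queries ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_residues(self) -> int:
        return len(self.resname)

    def residue_label(self, i: int) -> str:
        ic = self.icode[i].strip()
        return f"{self.chain_id[i]}:{self.resseq[i]}{ic}"

    def residue_labels(self) -> list[str]:
        return [self.residue_label(i) for i in range(self.n_residues)]

    def heavy_mask(self) -> np.ndarray:
        """Boolean atom mask excluding hydrogen/deuterium."""
        el = np.char.upper(self.element.astype(str))
        return (el != "H") & (el != "D")

    def residue_atom_indices(self, i: int) -> np.ndarray:
        return np.nonzero(self.atom_resindex == i)[0]

    def node_atom_indices(self, convention: str = "ca_p") -> np.ndarray:
        """One representative atom per residue.

        ``ca_p``: Cα for amino acids, P for nucleotides, first heavy atom
        otherwise.  ``centroid`` has no single atom; callers wanting centroids
        use :func:`node_positions` instead.
        """
        if convention != "ca_p":
            raise ValueError(f"unknown node-atom convention {convention!r}")
        out = np.empty(self.n_residues, dtype=int)
        for i in range(self.n_residues):
            idx = self.residue_atom_indices(i)
            if len(idx) == 0:
                raise StructureError(f"residue {self.residue_label(i)} has no atoms")
            names = self.atom_name[idx]
            want = "CA" if self.polymer[i] == "protein" else "P"
            hit = idx[names == want]
            if len(hit):
                out[i] = hit[0]
            else:
                heavy = idx[self.heavy_mask()[idx]]
                out[i] = heavy[0] if len(heavy) else idx[0]
        return out

    def node_positions(
        self, coords: np.ndarray | None = None, convention: str = "ca_p"
    ) -> np.ndarray:
        """(R, 3) node positions for one coordinate frame."""
        xyz = self.coords if coords is None else np.asarray(coords, dtype=float)
        if convention == "centroid":
            out = np.empty((self.n_residues, 3))
            heavy = self.heavy_mask()
            for i in range(self.n_residues):
                idx = self.residue_atom_indices(i)
                h = idx[heavy[idx]]
                out[i] = xyz[h if len(h) else idx].mean(axis=0)
            return out
        return xyz[self.node_atom_indices(convention)]

    def subset_atoms(self, atom_mask: np.ndarray) -> "Structure":
        """New Structure restricted to masked atoms (residues renumbered)."""
        atom_mask = np.asarray(atom_mask, dtype=bool)
        kept_res = np.unique(self.atom_resindex[atom_mask])
        remap = {old: new for new, old in enumerate(kept_res)}
        return Structure(
            atom_name=self.atom_name[atom_mask].copy(),
            element=self.element[atom_mask].copy(),
            coords=self.coords[atom_mask].copy(),
            occupancy=self.occupancy[atom_mask].copy(),
            bfactor=self.bfactor[atom_mask].copy(),
            atom_resindex=np.array(
                [remap[r] for r in self.atom_resindex[atom_mask]], dtype=int
            ),
            chain_id=self.chain_id[kept_res].copy(),
            resseq=self.resseq[kept_res].copy(),
            icode=self.icode[kept_res].copy(),
            resname=self.resname[kept_res].copy(),
            polymer=self.polymer[kept_res].copy(),
        )

    def residue_atom_mask(self, residues: Iterable[int]) -> np.ndarray:
        rs = set(int(r) for r in residues)
        return np.array([r in rs for r in self.atom_resindex], dtype=bool)


@dataclass
class Ensemble:
    """An ordered stack of coordinate frames over one topology."""

    topology: Structure
    frames: np.ndarray  # (T, A, 3) in Å
    state: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must be (T, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("an ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, t: int) -> Structure:
        s = self.topology
        return Structure(
            atom_name=s.atom_name, element=s.element,
            coords=self.frames[t].copy(),
            occupancy=s.occupancy, bfactor=s.bfactor,
            atom_resindex=s.atom_resindex, chain_id=s.chain_id,
            resseq=s.resseq, icode=s.icode, resname=s.resname,
            polymer=s.polymer,
        )


# ---------------------------------------------------------------------------
# gemmi-backed readers
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep a single altloc per atom name: highest occupancy, tie → 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for at in res:
        if at.name not in by_name:
            order.append(at.name)
        by_name.setdefault(at.name, []).append(at)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(min(group, key=lambda a: (-a.occ, a.altloc or "A")))
    return out


def _model_to_structure(model: gemmi.Model) -> Structure:
    atom_name, element, occ, bf, residx = [], [], [], [], []
    xyz: list[tuple[float, float, float]] = []
    chain_id, resseq, icode, resname = [], [], [], []
    for chain in model:
        for res in chain:
            ri = len(resname)
            chain_id.append(chain.name)
            resseq.append(res.seqid.num)
            icode.append((res.seqid.icode or " ").strip())
            resname.append(res.name)
            for at in _resolve_altlocs(res):
                atom_name.append(at.name)
                element.append(at.element.name)
                xyz.append((at.pos.x, at.pos.y, at.pos.z))
                occ.append(at.occ)
                bf.append(at.b_iso)
                residx.append(ri)
    if not atom_name:
        raise StructureError("no atoms found")
    polymer = np.array([classify_residue(r) for r in resname])
    return Structure(
        atom_name=np.array(atom_name), element=np.array(element),
        coords=np.array(xyz, dtype=float),
        occupancy=np.array(occ, dtype=float), bfactor=np.array(bf, dtype=float),
        atom_resindex=np.array(residx, dtype=int),
        chain_id=np.array(chain_id), resseq=np.array(resseq, dtype=int),
        icode=np.array(icode), resname=np.array(resname), polymer=polymer,
    )


def _read_gemmi(path: str, fmt: str | None) -> gemmi.Structure:
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown structure format {fmt!r} (use 'pdb' or 'mmcif')")
    except (RuntimeError, SystemError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return st


def load_structure(path: str, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A'); hydrogens are retained when present.
    """
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    return _model_to_structure(st[0])


def _load_multimodel_pdb(path: str, topology: Structure | None) -> Ensemble:
    st = _read_gemmi(path, None)
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    top = topology if topology is not None else _model_to_structure(st[0])
    frames = []
    for k, model in enumerate(st):
        s = _model_to_structure(model)
        if s.n_atoms != top.n_atoms:
            raise StructureError(
                f"model {k + 1} has {s.n_atoms} atoms, topology has {top.n_atoms}"
            )
        frames.append(s.coords)
    return Ensemble(topology=top, frames=np.array(frames))


def _load_mda_trajectory(path: str | Sequence[str], topology: Structure) -> Ensemble:
    import MDAnalysis as mda

    with tempfile.TemporaryDirectory() as tmp:
        toppdb = os.path.join(tmp, "top.pdb")
        write_multimodel_pdb(toppdb, topology, topology.coords[None])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(toppdb, path)
            if u.atoms.n_atoms != topology.n_atoms:
                raise StructureError(
                    f"trajectory has {u.atoms.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            # MDAnalysis always presents coordinates in Å
            frames = np.array([u.atoms.positions.copy().astype(float)
                               for _ in u.trajectory])
    return Ensemble(topology=topology, frames=frames)


def load_ensemble(
    topology: Structure | str,
    frames_source: str | Sequence[str],
    format: str | None = None,
    state: str = "",
) -> Ensemble:
    """Load a coordinate ensemble from a multi-model PDB, DCD or XTC file.

    ``topology`` may be a :class:`Structure` or a path to one.  Coordinates
    are stored in Å regardless of the source format's native unit.
    """
    if isinstance(topology, str):
        topology = load_structure(topology)
    if format is None:
        src = frames_source if isinstance(frames_source, str) else frames_source[0]
        ext = os.path.splitext(src)[1].lower().lstrip(".")
        format = {"pdb": "pdb", "ent": "pdb", "dcd": "dcd", "xtc": "xtc"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer trajectory format from {src!r}")
    if format == "pdb":
        if not isinstance(frames_source, str):
            ens = [_load_multimodel_pdb(p, topology) for p in frames_source]
            frames = np.concatenate([e.frames for e in ens])
            return Ensemble(topology=topology, frames=frames, state=state)
        e = _load_multimodel_pdb(frames_source, topology)
        return Ensemble(topology=e.topology, frames=e.frames, state=state)
    if format in ("dcd", "xtc"):
        e = _load_mda_trajectory(frames_source, topology)
        return Ensemble(topology=e.topology, frames=e.frames, state=state)
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_multimodel_pdb(
    path: str, structure: Structure, frames: np.ndarray | None = None
) -> None:
    """Write a (multi-model) PDB file; one MODEL record per frame."""
    if frames is None:
        frames = structure.coords[None]
    frames = np.asarray(frames, dtype=float)
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for t in range(frames.shape[0]):
            if multi:
                fh.write(f"MODEL     {t + 1:4d}\n")
            serial = 0
            # group atoms by residue so readers see contiguous residues
            atom_order = [a for ri in range(structure.n_residues)
                          for a in structure.residue_atom_indices(ri)]
            for a in atom_order:
                serial += 1
                ri = structure.atom_resindex[a]
                name = str(structure.atom_name[a])
                el = str(structure.element[a])
                # PDB atom-name column convention
                pname = f" {name:<3s}" if len(name) < 4 and len(el) == 1 else f"{name:<4s}"
                x, y, z = frames[t, a]
                fh.write(
                    "ATOM  {serial:5d} {name} {res:<3s} {ch:1s}{num:4d}{ic:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=serial % 100000, name=pname,
                        res=str(structure.resname[ri])[:3],
                        ch=str(structure.chain_id[ri])[:1] or "A",
                        num=int(structure.resseq[ri]),
                        ic=(str(structure.icode[ri]) or " ")[:1] or " ",
                        x=x, y=y, z=z,
                        occ=float(structure.occupancy[a]),
                        b=float(structure.bfactor[a]), el=el[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_mmcif(path: str, structure: Structure) -> None:
    """Write a minimal mmCIF rendering of a single conformer."""
    st = gemmi.Structure()
    st.name = "dyncon"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for ri in range(structure.n_residues):
        cid = str(structure.chain_id[ri])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = str(structure.resname[ri])
        res.seqid = gemmi.SeqId(int(structure.resseq[ri]),
                                (str(structure.icode[ri]) or " ")[0])
        for a in structure.residue_atom_indices(ri):
            at = gemmi.Atom()
            at.name = str(structure.atom_name[a])
            at.element = gemmi.Element(str(structure.element[a]))
            at.pos = gemmi.Position(*structure.coords[a])
            at.occ = float(structure.occupancy[a])
            at.b_iso = float(structure.bfactor[a])
            res.add_atom(at)
        chains[cid].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))
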