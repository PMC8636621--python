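import numpy as np
import pytest

from dyncon.structure import Ensemble, Structure


def make_structure(
    coords,
    names=None,
    elements=None,
    atom_resindex=None,
    chains=None,
    resids=None,
    resnames=None,
    polymers=None,
    icodes=None,
):
    """Hand-built Structure; one residue per atom unless atom_resindex given."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    atom_resindex = (np.arange(n) if atom_resindex is None
                     else np.asarray(atom_resindex, dtype=int))
    nres = atom_resindex.max() + 1
    resnames = np.array(resnames or ["ALA"] * nres)
    polymers = (np.array(polymers) if polymers is not None else
                np.array(["protein"] * nres))
    return Structure(
        atom_name=np.array(names or ["CA"] * n),
        element=np.array(elements or ["C"] * n),
        coords=coords,
        occupancy=np.ones(n),
        bfactor=np.zeros(n),
        atom_resindex=atom_resindex,
        chain_id=np.array(chains or ["A"] * nres),
        resseq=np.array(resids if resids is not None
                        else 1 + 2 * np.arange(nres)),
        icode=np.array(icodes or [""] * nres),
        resname=resnames,
        polymer=polymers,
    )


def static_ensemble(structure, n_frames=4, state=""):
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return Ensemble(topology=structure, frames=frames, state=state)


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A 326      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A 326      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB AALA A 326      12.000   7.000  -4.000  0.60  0.00           C
ATOM      4  CB BALA A 326      12.100   7.100  -4.100  0.40  0.00           C
ATOM      5  N   GLY A 327       9.500   5.000  -4.000  1.00  0.00           N
ATOM      6  CA  GLY A 327       9.800   4.500  -2.700  1.00  0.00           C
ATOM      7  P    DA B   5       1.000   2.000   3.000  1.00  0.00           P
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return str(path)
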