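"""Structural metrics: SASA/BSA, ensemble B-factors, duplex rotation, CCC.

Solvent-accessible surface area uses the Shrake–Rupley point-sampling
algorithm with Bondi van der Waals radii and a 1.4 Å water probe; buried
surface area of a group pair is the unhalved ΔSASA,

    BSA(A, B) = SASA(A) + SASA(B) − SASA(A ∪ B).

Ensemble B-factors are B_i = (8π²/3)⟨|Δr_i|²⟩ of the residue node atom.
Map-to-model cross-correlation simulates a density from the model as a sum
of atom-centred Gaussians (σ = 0.225·resolution, amplitude ∝ atomic
number) on the experimental grid and correlates the two densities over the
simulated envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._geom import kabsch, rotation_angle_axis, superpose, superpose_frames
from .selections import Selection, select_residues
from .structure import Ensemble, Structure

__all__ = [
    "AreaReport",
    "DensityMap",
    "BONDI_RADII",
    "sasa",
    "buried_surface_area",
    "computed_bfactors",
    "duplex_rotation_angle",
    "simulate_density",
    "map_model_ccc",
    "read_ccp4_map",
]

# Bondi (1964) van der Waals radii, Å
BONDI_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75, "FE": 1.63, "MN": 1.61,
    "CA": 2.31,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclass
class AreaReport:
    """Per-atom / per-residue solvent-accessible areas in Å²."""

    atom_area: np.ndarray
    residue_area: np.ndarray
    probe: float
    n_points: int
    total: float = 0.0

    def __post_init__(self) -> None:
        self.total = float(self.atom_area.sum())


def _vdw_radii(structure: Structure, atom_idx: np.ndarray,
               radii: dict | None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    out = np.empty(len(atom_idx))
    unknown = set()
    for k, a in enumerate(atom_idx):
        el = str(structure.element[a]).upper()
        if el in table:
            out[k] = table[el]
        else:
            out[k] = DEFAULT_RADIUS
            unknown.add(el)
    if unknown:
        warnings.warn(f"unknown element(s) {sorted(unknown)}; "
                      f"using default vdW radius {DEFAULT_RADIUS} Å")
    return out


def sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
    radii: dict | None = None,
    atom_mask: np.ndarray | None = None,
) -> AreaReport:
    """Shrake–Rupley solvent-accessible surface area.

    For each (heavy) atom, the fraction of ``n_points`` sphere points at
    radius r_vdW + probe not buried inside any neighbour's expanded sphere,
    times the expanded-sphere area.  Hydrogens are ignored.
    """
    heavy = structure.heavy_mask()
    if atom_mask is not None:
        heavy = heavy & np.asarray(atom_mask, dtype=bool)
    idx = np.nonzero(heavy)[0]
    if len(idx) == 0:
        raise ValueError("no atoms selected for SASA")
    xyz = structure.coords[idx]
    rad = _vdw_radii(structure, idx, radii) + probe
    pts = sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = rad.max()
    atom_area = np.zeros(structure.n_atoms)
    for k in range(len(idx)):
        neigh = [m for m in tree.query_ball_point(xyz[k], rad[k] + rmax)
                 if m != k]
        surf = xyz[k] + rad[k] * pts
        if neigh:
            nb_xyz = xyz[neigh]
            nb_rad = rad[neigh]
            d2 = ((surf[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(-1)
            exposed = np.all(d2 > (nb_rad ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        atom_area[idx[k]] = frac * 4.0 * np.pi * rad[k] ** 2
    residue_area = np.zeros(structure.n_residues)
    np.add.at(residue_area, structure.atom_resindex, atom_area)
    return AreaReport(atom_area=atom_area, residue_area=residue_area,
                      probe=probe, n_points=n_points)


def buried_surface_area(
    structure: Structure,
    group_a: Selection | str | set,
    group_b: Selection | str | set,
    subgroups: dict[str, Selection | str | set] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
    halved: bool = False,
):
    """Buried surface area between two residue groups, with decomposition.

    BSA = SASA(A) + SASA(B) − SASA(A∪B), reported unhalved by default
    (``halved=True`` divides by two for the per-side convention).  Each
    subgroup S ⊆ A contributes BSA(S, B), i.e. the same formula with S in
    place of A; percentages are relative to the total.
    """
    res_a = _as_residues(structure, group_a)
    res_b = _as_residues(structure, group_b)
    if not res_a or not res_b:
        raise ValueError("groups must be nonempty")
    if res_a & res_b:
        raise ValueError("groups must be disjoint")

    def _area(residues: set) -> float:
        sub = structure.subset_atoms(structure.residue_atom_mask(residues))
        return sasa(sub, probe=probe, n_points=n_points).total

    sa_a, sa_b = _area(res_a), _area(res_b)
    sa_ab = _area(res_a | res_b)
    scale = 0.5 if halved else 1.0
    total = scale * (sa_a + sa_b - sa_ab)
    decomposition = {}
    if subgroups:
        for name, sel in subgroups.items():
            res_s = _as_residues(structure, sel)
            if not res_s <= res_a:
                raise ValueError(f"subgroup {name!r} is not contained in group A")
            bsa_s = scale * (_area(res_s) + sa_b - _area(res_s | res_b))
            decomposition[name] = {
                "bsa": bsa_s,
                "percent": 100.0 * bsa_s / total if total > 0 else 0.0,
            }
    return {"bsa": total, "sasa_a": sa_a, "sasa_b": sa_b,
            "sasa_complex": sa_ab, "subgroups": decomposition}


def _as_residues(structure: Structure, sel) -> set[int]:
    if isinstance(sel, (set, frozenset)):
        return set(int(i) for i in sel)
    return set(select_residues(structure, sel))


def computed_bfactors(
    ensemble: Ensemble, node_atom: str = "ca_p",
    superpose_iterations: int = 2,
) -> np.ndarray:
    """Per-residue B = (8π²/3)·⟨|Δr|²⟩ of the node atom, in Å²."""
    if ensemble.n_frames < 2:
        raise ValueError("B-factors need at least two frames")
    top = ensemble.topology
    if node_atom == "centroid":
        traj = np.array([top.node_positions(f, "centroid")
                         for f in ensemble.frames])
    else:
        atoms = top.node_atom_indices(node_atom)
        traj = ensemble.frames[:, atoms, :]
    traj = superpose_frames(traj, iterations=superpose_iterations)
    delta = traj - traj.mean(axis=0, keepdims=True)
    msf = (delta ** 2).sum(axis=2).mean(axis=0)
    return (8.0 * np.pi ** 2 / 3.0) * msf


def duplex_rotation_angle(
    frame_a: Structure,
    frame_b: Structure,
    align_on: Selection | str | set,
    duplex: Selection | str | set,
):
    """Rotation (degrees, plus axis) of a duplex between two conformers.

    Frame b is first least-squares superposed onto frame a using the
    ``align_on`` atoms; the optimal rotation carrying the duplex atoms of a
    onto their counterparts in b is then extracted.
    """
    res_align_a = sorted(_as_residues(frame_a, align_on))
    res_align_b = sorted(_as_residues(frame_b, align_on))
    res_dup_a = sorted(_as_residues(frame_a, duplex))
    res_dup_b = sorted(_as_residues(frame_b, duplex))
    if res_align_a != res_align_b or res_dup_a != res_dup_b:
        raise ValueError("selections resolve differently in the two frames")

    def _atoms(s: Structure, residues) -> np.ndarray:
        mask = s.residue_atom_mask(residues) & s.heavy_mask()
        return np.nonzero(mask)[0]

    ia, ib = _atoms(frame_a, res_align_a), _atoms(frame_b, res_align_b)
    da, db = _atoms(frame_a, res_dup_a), _atoms(frame_b, res_dup_b)
    if len(ia) != len(ib) or len(da) != len(db):
        raise ValueError("atom counts differ between frames")
    for sel_atoms, what in ((ia, "alignment"), (da, "duplex")):
        pts = frame_a.coords[sel_atoms]
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
            raise ValueError(f"{what} selection needs ≥ 3 non-collinear atoms")

    R_align, t_align = kabsch(frame_b.coords[ib], frame_a.coords[ia])
    dup_b_aligned = frame_b.coords[db] @ R_align.T + t_align
    R_dup, _ = kabsch(frame_a.coords[da], dup_b_aligned)
    angle, axis = rotation_angle_axis(R_dup)
    return angle, axis


# ---------------------------------------------------------------------------
# density maps and map-to-model cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Axis-aligned orthogonal density grid."""

    data: np.ndarray              # (nx, ny, nz)
    voxel: float                  # Å
    origin: np.ndarray            # (3,) Å position of voxel (0,0,0)
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density grid must be 3-D and nonempty")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")


def read_ccp4_map(path: str, resolution: float | None = None) -> DensityMap:
    """Read an MRC/CCP4 density map (orthogonal cells only)."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    grid = m.grid
    cell = grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("only orthogonal map cells are supported")
    data = np.array(grid, copy=True)
    vx = cell.a / grid.nu
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)], dtype=float)
    return DensityMap(data=data, voxel=vx, origin=origin, resolution=resolution)


_ATOMIC_NUMBER_CACHE: dict[str, int] = {}


def _atomic_number(element: str) -> int:
    el = element.upper()
    if el not in _ATOMIC_NUMBER_CACHE:
        z = gemmi.Element(element).atomic_number
        _ATOMIC_NUMBER_CACHE[el] = z if z > 0 else 6
    return _ATOMIC_NUMBER_CACHE[el]


def simulate_density(
    structure: Structure,
    grid_shape: tuple[int, int, int],
    voxel: float,
    origin: np.ndarray,
    resolution: float,
    sigma_factor: float = 0.225,
) -> DensityMap:
    """Model density: atom-centred Gaussians, σ = sigma_factor·resolution."""
    sigma = sigma_factor * resolution
    data = np.zeros(grid_shape)
    reach = 3.0 * sigma
    origin = np.asarray(origin, dtype=float)
    shape = np.array(grid_shape)
    for a in range(structure.n_atoms):
        z = _atomic_number(str(structure.element[a]))
        pos = (structure.coords[a] - origin) / voxel
        lo = np.maximum(np.ceil(pos - reach / voxel).astype(int), 0)
        hi = np.minimum(np.floor(pos + reach / voxel).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        d2 = ((gx - pos[0]) ** 2 + (gy - pos[1]) ** 2
              + (gz - pos[2]) ** 2) * voxel ** 2
        data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += \
            z * np.exp(-d2 / (2.0 * sigma ** 2))
    return DensityMap(data=data, voxel=voxel, origin=origin,
                      resolution=resolution)


def map_model_ccc(
    structure: Structure,
    density: DensityMap,
    resolution: float,
    sigma_factor: float = 0.225,
    envelope: str = "sim_threshold",
    envelope_fraction: float = 0.01,
) -> float:
    """Pearson correlation between experimental and model-simulated density.

    By default the correlation runs over voxels where the simulated density
    exceeds ``envelope_fraction`` of its maximum (whole-box CCC is dominated
    by empty solvent); ``envelope='about_mean'`` correlates every voxel.
    """
    lo = (structure.coords.min(axis=0) - density.origin) / density.voxel
    hi = (structure.coords.max(axis=0) - density.origin) / density.voxel
    if np.any(lo < -1) or np.any(hi > np.array(density.data.shape)):
        raise ValueError("model lies outside the density grid")
    sim = simulate_density(structure, density.data.shape, density.voxel,
                           density.origin, resolution, sigma_factor)
    x = sim.data.ravel()
    y = density.data.ravel()
    if envelope == "sim_threshold":
        mask = x > envelope_fraction * x.max()
        if mask.sum() < 2:
            raise ValueError("simulated envelope is empty")
        x, y = x[mask], y[mask]
    elif envelope != "about_mean":
        raise ValueError(f"unknown envelope mode {envelope!r}")
    x = x - x.mean()
    y = y - y.mean()
    if (y ** 2).sum() == 0:
        # experimental map is flat inside the model envelope: no correlation
        return 0.0
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance simulated density")
    return float(np.dot(x, y) / denom)
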