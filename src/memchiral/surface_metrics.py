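"""SASA (rolling-ball), near-protein interface metrics, membrane composition.

The SASA implementation is Shrake-Rupley with a deterministic golden-spiral
point set: each selected atom's van-der-Waals sphere is inflated by the probe
radius (default 1.4 A, a water molecule), sampled with n points, and a sample
point counts as exposed when it lies outside every other selected atom's
inflated sphere. Determinism over random sphere sampling is deliberate: the
same structure always yields the same area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import SelectionSpec, StructureModel

logger = logging.getLogger(__name__)

_DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
_DEFAULT_RADIUS = 1.70

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

POLAR_RESIDUES = frozenset({
    "SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS", "LYS", "ARG",
    "ASP", "GLU",
})


@dataclass
class RadiiTable:
    """Van-der-Waals radii by element plus the solvent probe radius (A)."""

    radii: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RADII))
    default: float = _DEFAULT_RADIUS
    probe: float = 1.4

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element.capitalize())
        if r is None:
            logger.warning("unknown element %r: using default radius %.2f",
                           element, self.default)
            return self.default
        return r


@dataclass
class CompositionProfile:
    """Patch-normalised membrane composition metrics."""

    membrane_area: float          # A^2
    protein_count: int            # distinct protein chains
    protein_density: float        # proteins per 10^3 A^2
    cholesterol_mol_fraction: float
    polar_residue_fraction: float
    hydrophobicity_index: float   # mean Kyte-Doolittle over protein residues
    thickness: float | None       # A; None if not computable


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(model: StructureModel, spec: SelectionSpec | None = None,
         radii: RadiiTable | None = None, n_sphere_points: int = 960
         ) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (total area, per-atom areas) in A^2 for the selected atoms; the
    per-atom areas sum exactly to the total. Occlusion is evaluated within
    the selection only.
    """
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be >= 92")
    radii = radii or RadiiTable()
    idx = _selection_indices(model, spec)
    coords = np.array([[model.atoms[i].x, model.atoms[i].y, model.atoms[i].z]
                       for i in idx])
    inflated = np.array([radii.radius_of(model.atoms[i].element) + radii.probe
                         for i in idx])
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = inflated.max()
    areas = np.zeros(len(idx))
    for a in range(len(idx)):
        # neighbours within r_a + r_b are the only possible occluders
        cand = np.array(tree.query_ball_point(coords[a],
                                              inflated[a] + max_r),
                        dtype=int)
        cand = cand[cand != a]
        if cand.size:
            d = np.linalg.norm(coords[cand] - coords[a], axis=1)
            cand = cand[d <= inflated[a] + inflated[cand]]
        if cand.size:
            pts = coords[a] + inflated[a] * sphere
            d2 = cdist(pts, coords[cand], "sqeuclidean")
            exposed = np.all(d2 > inflated[cand][None, :] ** 2, axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[a] = 4.0 * np.pi * inflated[a] ** 2 * frac
    return float(areas.sum()), areas


def _selection_indices(model: StructureModel,
                       spec: SelectionSpec | None) -> list[int]:
    from .structure_io import _BACKBONE_NAMES

    if spec is None or spec.mode == "all":
        idx = list(range(len(model.atoms)))
    elif spec.mode == "protein":
        idx = model.component_indices("protein")
    elif spec.mode == "lipid":
        idx = model.component_indices("lipid")
    elif spec.mode == "backbone":
        prot = set(model.component_indices("protein"))
        idx = sorted(i for i in prot if model.atoms[i].name in _BACKBONE_NAMES)
    else:
        wanted = {r.upper() for r in spec.custom_residues}
        idx = [i for i, a in enumerate(model.atoms)
               if a.residue_name.upper() in wanted]
    if not idx:
        raise ValueError(f"empty selection (mode={getattr(spec, 'mode', 'all')})")
    return idx


def near_protein_metrics(model: StructureModel, radii: RadiiTable | None = None,
                         cutoff: float = 5.0, voxel: float = 0.5,
                         n_sphere_points: int = 960,
                         surface_distance: bool = False) -> dict[str, float]:
    """Surface area, volume and count of non-protein atoms near the protein.

    The near set is every non-protein atom whose centre lies within ``cutoff``
    of any protein atom centre (with ``surface_distance=True``, within cutoff
    of the protein vdW surface instead). The area is the sum of the near
    atoms' per-atom SASA contributions computed in the full-model context;
    the volume is the voxelised union of their vdW spheres.
    """
    radii = radii or RadiiTable()
    prot_idx = model.component_indices("protein")
    if not prot_idx:
        raise ValueError("no protein component")
    coords = model.coords
    prot_set = set(prot_idx)
    non_prot = [i for i in range(len(model.atoms)) if i not in prot_set]
    if not non_prot:
        raise ValueError("no non-protein atoms")
    prot_tree = cKDTree(coords[prot_idx])
    near: list[int] = []
    for i in non_prot:
        d, j = prot_tree.query(coords[i])
        if surface_distance:
            d = d - radii.radius_of(model.atoms[prot_idx[j]].element)
        if d <= cutoff:
            near.append(i)
    if not near:
        return {"near_surface_area": 0.0, "near_volume": 0.0,
                "near_atom_count": 0}
    _, per_atom = sasa(model, None, radii=radii,
                       n_sphere_points=n_sphere_points)
    near_area = float(per_atom[near].sum())
    near_vol = _union_sphere_volume(
        coords[near],
        np.array([radii.radius_of(model.atoms[i].element) for i in near]),
        voxel)
    return {"near_surface_area": near_area, "near_volume": near_vol,
            "near_atom_count": len(near)}


def _union_sphere_volume(centers: np.ndarray, radii_arr: np.ndarray,
                         voxel: float) -> float:
    """Volume of a union of spheres by voxel-centre membership counting."""
    pad = radii_arr.max() + voxel
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    axes = [np.arange(lo[d] + voxel / 2, hi[d], voxel) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(grid)
    inside = np.zeros(len(grid), dtype=bool)
    for c, r in zip(centers, radii_arr):
        inside[tree.query_ball_point(c, r)] = True
    return float(inside.sum()) * voxel ** 3


def membrane_thickness(model: StructureModel) -> float:
    """Bilayer thickness as the z-separation of leaflet phosphorus planes.

    Lipid phosphorus atoms are split into leaflets by the sign of z relative
    to their overall mean z; the thickness is the difference of the two
    leaflet means. Assumes the bilayer normal is z (patches are built in the
    xy-plane).
    """
    p_z = [a.z for i, a in enumerate(model.atoms)
           if model.component_of.get(i) in ("lipid", "sterol")
           and a.element.upper() == "P"]
    if not p_z:
        raise ValueError("monolayer or missing headgroups: no lipid P atoms")
    p_z = np.array(p_z)
    mid = p_z.mean()
    upper = p_z[p_z > mid]
    lower = p_z[p_z < mid]
    if upper.size == 0 or lower.size == 0:
        raise ValueError("monolayer or missing headgroups: one leaflet empty")
    return float(upper.mean() - lower.mean())


def composition_profile(model: StructureModel,
                        membrane_area: float = 10000.0) -> CompositionProfile:
    """Patch-normalised composition metrics of a classified membrane model.

    Protein count is the number of distinct chains containing protein atoms
    (a membrane protein = one chain); density is per 10^3 A^2 of patch area.
    Cholesterol fraction is sterol molecules over all lipid+sterol molecules,
    a molecule being a distinct (chain, residue number, residue name).
    """
    if membrane_area <= 0:
        raise ValueError("invalid area")
    chains = {a.chain_id for i, a in enumerate(model.atoms)
              if model.component_of.get(i) == "protein"}
    lipid_mols, sterol_mols = set(), set()
    residues: dict[tuple, str] = {}
    for i, a in enumerate(model.atoms):
        comp = model.component_of.get(i)
        key = (a.chain_id, a.residue_seq, a.residue_name)
        if comp == "lipid":
            lipid_mols.add(key)
        elif comp == "sterol":
            sterol_mols.add(key)
        elif comp == "protein":
            residues[key] = a.residue_name.upper()
    n_lip = len(lipid_mols) + len(sterol_mols)
    chol = len(sterol_mols) / n_lip if n_lip else 0.0
    if residues:
        names = list(residues.values())
        polar = sum(1 for r in names if r in POLAR_RESIDUES) / len(names)
        kd = [KYTE_DOOLITTLE[r] for r in names if r in KYTE_DOOLITTLE]
        hydro = float(np.mean(kd)) if kd else float("nan")
    else:
        polar, hydro = 0.0, float("nan")
    try:
        thick = membrane_thickness(model)
    except ValueError:
        thick = None
    return CompositionProfile(
        membrane_area=membrane_area,
        protein_count=len(chains),
        protein_density=len(chains) / (membrane_area / 1000.0),
        cholesterol_mol_fraction=chol,
        polar_residue_fraction=polar,
        hydrophobicity_index=hydro,
        thickness=thick,
    )
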