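"""Fixed-column PDB reading/writing, component classification, selections.

Only the ATOM/HETATM coordinate subset of PDB v3.3 is handled: no mmCIF,
trajectories, bonds or symmetry. Atom order is preserved everywhere because
the chiral-moment descriptor depends on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: 20 standard amino acids plus common His tautomer names and selenomethionine.
PROTEIN_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
})
STEROL_RESIDUES = frozenset({"CHL", "CHL1", "CLR", "ERG"})
LIPID_RESIDUES = frozenset({
    "POPC", "POPE", "POPS", "POPG", "DPPC", "DOPC", "SM", "PSM", "SSM",
})
WATER_RESIDUES = frozenset({"HOH", "WAT", "TIP3"})
ION_RESIDUES = frozenset({"NA", "CL", "K", "CA"})

#: Two-letter element symbols checked before single-letter fallback.
_TWO_LETTER_ELEMENTS = frozenset({"CL", "NA", "MG", "FE", "ZN", "BR"})


@dataclass
class Atom:
    """One coordinate record.

    Coordinates are in Angstroms in an arbitrary frame; ``element`` is always
    non-empty (inferred from the atom name when columns 77-78 are blank).
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    x: float
    y: float
    z: float
    element: str
    record: str = "ATOM"

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class StructureModel:
    """A parsed structure: atoms in file order plus per-atom component labels.

    ``component_of`` maps atom index -> one of {protein, lipid, sterol, water,
    ion, other}; it is empty until :func:`classify_components` runs.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)
    component_of: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def component_indices(self, component: str) -> list[int]:
        """Atom indices labeled with ``component``.

        ``lipid`` includes sterols (they are bilayer constituents for
        bilayer-wide metrics); use ``sterol`` for the sterol subset alone.
        """
        if component == "lipid":
            wanted = {"lipid", "sterol"}
        else:
            wanted = {component}
        return [i for i, a in enumerate(self.atoms)
                if self.component_of.get(i) in wanted]


@dataclass
class SelectionSpec:
    """Which atoms enter a computation.

    mode ``backbone`` means protein N/CA/C/O atoms; ``custom`` selects by
    residue name and requires a non-empty ``custom_residues`` set.
    """

    mode: str = "all"
    custom_residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        valid = {"all", "protein", "lipid", "backbone", "custom"}
        if self.mode not in valid:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "custom" and not self.custom_residues:
            raise ValueError("custom selection requires custom_residues")


class PDBParseError(ValueError):
    pass


def _infer_element(atom_name: str) -> str:
    """Element from the atom-name columns when element columns are blank.

    Digits are stripped; a leading two-letter symbol from a small metal/halide
    set is honoured, otherwise the first alphabetic character wins.
    """
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return "X"
    if stripped[:2].upper() in _TWO_LETTER_ELEMENTS:
        return stripped[:2].upper().capitalize()
    return stripped[0].upper()


def parse_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records from a PDB file into a :class:`StructureModel`.

    Fixed 1-based columns: name 13-16, resName 18-21 (4th char admits long
    lipid names), x/y/z 31-38/39-46/47-54, element 77-78. Only the first
    MODEL block is read (a warning is logged for extra ones); altLoc values
    other than blank/'A' are skipped. Raises :class:`PDBParseError` for files
    with no coordinate records or malformed coordinate fields.
    """
    path = Path(path)
    atoms: list[Atom] = []
    in_later_model = False
    model_count = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                model_count += 1
                if model_count > 1:
                    in_later_model = True
                continue
            if rec == "ENDMDL":
                continue
            if rec not in ("ATOM", "HETATM") or in_later_model:
                continue
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            name = line[12:16].strip()
            res_name = line[17:21].strip()
            chain = line[21:22].strip() or " "
            try:
                res_seq = int(line[22:26])
            except ValueError:
                res_seq = 0
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"malformed record at line {lineno} of {path.name}"
                ) from exc
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise PDBParseError(
                    f"malformed record at line {lineno} of {path.name}"
                )
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name)
            element = element.capitalize()
            atoms.append(Atom(serial, name, res_name, chain, res_seq,
                              x, y, z, element, rec))
    if model_count > 1:
        logger.warning("%s: %d MODEL blocks; only the first was read",
                       path.name, model_count)
    if not atoms:
        raise PDBParseError(f"empty structure: no coordinate records in {path}")
    return StructureModel(id=path.stem, atoms=atoms)


def classify_components(model: StructureModel) -> StructureModel:
    """Label every atom as protein/lipid/sterol/water/ion/other by residue name.

    Sterols are tracked separately from lipids so the cholesterol mole
    fraction is computable, but count as lipid for bilayer-wide selections.
    Unknown residue names become ``other`` (logged, never an error).
    """
    unknown: set[str] = set()
    for i, atom in enumerate(model.atoms):
        res = atom.residue_name.upper()
        if res in PROTEIN_RESIDUES:
            label = "protein"
        elif res in STEROL_RESIDUES:
            label = "sterol"
        elif res in LIPID_RESIDUES:
            label = "lipid"
        elif res in WATER_RESIDUES:
            label = "water"
        elif res in ION_RESIDUES:
            label = "ion"
        else:
            label = "other"
            unknown.add(res)
        model.component_of[i] = label
    if unknown:
        logger.info("%s: unclassified residues -> other: %s",
                    model.id, sorted(unknown))
    return model


_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def select_atoms(model: StructureModel, spec: SelectionSpec) -> "PointCloud":
    """Coordinates of matching atoms, file order preserved.

    Raises ``ValueError`` on an empty selection.
    """
    from .descriptors import PointCloud  # avoid import cycle

    if spec.mode == "all":
        idx = list(range(len(model.atoms)))
    elif spec.mode == "protein":
        idx = model.component_indices("protein")
    elif spec.mode == "lipid":
        idx = model.component_indices("lipid")
    elif spec.mode == "backbone":
        prot = set(model.component_indices("protein"))
        idx = [i for i in prot if model.atoms[i].name in _BACKBONE_NAMES]
        idx.sort()
    else:  # custom
        wanted = {r.upper() for r in spec.custom_residues}
        idx = [i for i, a in enumerate(model.atoms)
               if a.residue_name.upper() in wanted]
    if not idx:
        raise ValueError(f"empty selection (mode={spec.mode}) on {model.id}")
    coords = np.array([[model.atoms[i].x, model.atoms[i].y, model.atoms[i].z]
                       for i in idx])
    return PointCloud(coords)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column ATOM/HETATM records; round-trips coords to 0.001 A.

    Raises ``ValueError`` for an empty model or coordinates whose magnitude
    does not fit the 8.3 fixed field (|coord| >= 10000).
    """
    if not model.atoms:
        raise ValueError("empty model")
    lines = []
    for atom in model.atoms:
        for v in (atom.x, atom.y, atom.z):
            if abs(v) >= 10000:
                raise ValueError(f"unrepresentable coordinate {v!r}")
        name = atom.name
        # PDB convention: 1-3 char names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"{atom.record:<6s}{atom.serial % 100000:>5d} {name_field}"
            f" {atom.residue_name:<4s}{atom.chain_id:1s}"
            f"{atom.residue_seq % 10000:>4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
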