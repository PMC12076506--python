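"""Molecule and protein data model plus SDF/PDB readers and writers.

A ligand is held as a plain ``Molecule3D``: element symbols, Cartesian
coordinates in Angstrom, and a symmetric categorical bond matrix.  The protein
pocket is reduced to the heavy-atom point cloud a clash-guidance term needs
(``ProteinContext``), with per-atom residue labels retained for interaction
bookkeeping.  RDKit handles SDF records; Biopython handles PDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem

from .errors import EmptyContextError, FormatError

# Bond categories: index into this tuple is the code stored in Molecule3D.bonds.
BOND_TYPES = ("none", "single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}
_BOND_CODE = {v: k for k, v in _RDKIT_BOND.items()}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Molecule3D:
    """A 3D molecule: atom types A, positions R (Angstrom), bonds B.

    ``bonds[i, j]`` is a code into :data:`BOND_TYPES`; the matrix is symmetric
    with a zero diagonal.  Hydrogens are kept if the source had them.
    """

    atom_types: list[str]
    positions: np.ndarray
    bonds: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int)
        n = len(self.atom_types)
        if n < 1:
            raise ValueError("molecule must have at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.bonds.shape != (n, n):
            raise ValueError(f"bond matrix shape {self.bonds.shape} != ({n}, {n})")
        if not np.array_equal(self.bonds, self.bonds.T):
            raise ValueError("bond matrix must be symmetric")
        if np.any(np.diag(self.bonds) != 0):
            raise ValueError("bond matrix diagonal must be zero")
        if self.bonds.min() < 0 or self.bonds.max() >= len(BOND_TYPES):
            raise ValueError("bond codes out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_types)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.atom_types) if s != "H"],
                        dtype=int)

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Rigidly transform positions: r -> rotation @ r + translation."""
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, positions=pos)


@dataclass
class ProteinContext:
    """Protein heavy atoms as a labeled point cloud.

    ``sigma`` is the smoothing scale of the soft-min surface field (Angstrom);
    ``clash_threshold`` is the minimum tolerated ligand-surface distance.
    """

    atom_positions: np.ndarray
    residue_labels: list[str]
    elements: list[str] = field(default_factory=list)
    sigma: float = 1.0
    clash_threshold: float = 2.0

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        if self.atom_positions.ndim != 2 or self.atom_positions.shape[1] != 3:
            raise ValueError("atom_positions must be P x 3")
        p = self.atom_positions.shape[0]
        if p < 1:
            raise EmptyContextError("protein context has no atoms")
        if len(self.residue_labels) != p:
            raise ValueError("residue_labels length mismatch")
        if not self.elements:
            self.elements = ["C"] * p
        if len(self.elements) != p:
            raise ValueError("elements length mismatch")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.clash_threshold < 0:
            raise ValueError("clash_threshold must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.atom_positions.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinContext":
        pos = self.atom_positions @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, atom_positions=pos)


# ---------------------------------------------------------------------------
# RDKit conversion


def to_rdkit(mol: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit Mol (with one conformer) from a Molecule3D."""
    rw = Chem.RWMol()
    for sym in mol.atom_types:
        rw.AddAtom(Chem.Atom(sym))
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            code = int(mol.bonds[i, j])
            if code:
                rw.AddBond(i, j, _RDKIT_BOND[code])
    conf = Chem.Conformer(n)
    for i, xyz in enumerate(mol.positions):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    m = rw.GetMol()
    m.AddConformer(conf, assignId=True)
    if mol.name:
        m.SetProp("_Name", mol.name)
    if sanitize:
        Chem.SanitizeMol(m)
    return m


def from_rdkit(rdmol: Chem.Mol) -> Molecule3D:
    """Convert an RDKit Mol with a conformer into a Molecule3D."""
    if rdmol.GetNumConformers() == 0:
        raise FormatError("molecule has no conformer")
    n = rdmol.GetNumAtoms()
    types = [a.GetSymbol() for a in rdmol.GetAtoms()]
    pos = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    bonds = np.zeros((n, n), dtype=int)
    for b in rdmol.GetBonds():
        code = _BOND_CODE.get(b.GetBondType(), 1)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds[i, j] = bonds[j, i] = code
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return Molecule3D(types, pos, bonds, name=name)


# ---------------------------------------------------------------------------
# SDF

def iter_ligands(path: str | Path) -> Iterator[Molecule3D]:
    """Iterate over all parseable records of a (possibly multi-record) SDF."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for rdmol in supplier:
        if rdmol is None:
            continue
        yield from_rdkit(rdmol)


def read_ligand(path: str | Path) -> Molecule3D:
    """Read the first record of an SDF file.

    Raises :class:`FormatError` for unparsable or empty files; 2D-only
    coordinates are allowed but flagged with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        rdmol = next(iter(supplier), None)
    except OSError as exc:
        raise FormatError(f"cannot read SDF {path}: {exc}") from exc
    if rdmol is None:
        raise FormatError(f"no parseable SDF record in {path}")
    mol = from_rdkit(rdmol)
    if np.allclose(mol.positions[:, 2], 0.0) and mol.n_atoms > 3:
        warnings.warn(f"{path}: coordinates look 2D (all z == 0)", stacklevel=2)
    return mol


def write_ligands(mols: Sequence[Molecule3D] | Molecule3D, path: str | Path) -> None:
    """Write one or more molecules to an SDF (V2000)."""
    if isinstance(mols, Molecule3D):
        mols = [mols]
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(to_rdkit(mol, sanitize=True))
    finally:
        writer.close()


# Alias used by the CLI layer.
write_ligand = write_ligands


# ---------------------------------------------------------------------------
# PDB

def read_protein(path: str | Path, drop_waters: bool = True,
                 sigma: float = 1.0, clash_threshold: float = 2.0) -> ProteinContext:
    """Read a PDB file into a ProteinContext (heavy atoms only).

    Waters (HOH/WAT/...) are removed by default, matching the convention of
    excluding crystallographic waters from generation.  Alternate locations
    other than blank/'A' are dropped; insertion codes are kept inside the
    residue label (``chain:resname:resseq[icode]``).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("prot", str(path))
    except Exception as exc:  # Biopython raises assorted types
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc

    positions, labels, elements = [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if drop_waters and resname in _WATER_RESNAMES:
                    continue
                het, resseq, icode = residue.get_id()
                label = f"{chain.id}:{resname}:{resseq}{icode.strip()}"
                for atom in residue:
                    if atom.element in ("H", "D"):
                        continue
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    positions.append(atom.get_coord())
                    labels.append(label)
                    elements.append(atom.element if atom.element else "C")
        break  # first model only
    if not positions:
        raise EmptyContextError(f"no protein heavy atoms in {path}")
    return ProteinContext(np.array(positions, dtype=float), labels, elements,
                          sigma=sigma, clash_threshold=clash_threshold)


def write_protein(ctx: ProteinContext, path: str | Path, resname: str = "POC") -> None:
    """Write a ProteinContext as a minimal PDB (one residue per point unless labeled)."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("ctx")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i, (pos, elem) in enumerate(zip(ctx.atom_positions, ctx.elements)):
        sb.init_residue(resname, " ", i + 1, " ")
        name = f"{elem}{(i % 99) + 1}"[:4]
        sb.init_atom(name, np.asarray(pos, dtype=float), 0.0, 1.0, " ",
                     name, i + 1, elem)
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Fragments

def _components(bonds: np.ndarray) -> list[list[int]]:
    """Connected components of the bond graph, in order of first atom index."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix((bonds != 0).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(idx)
    return [comps[k] for k in sorted(comps, key=lambda k: min(comps[k]))]


def largest_fragment(mol: Molecule3D) -> Molecule3D:
    """Return the connected component with the most heavy atoms.

    Ties are broken toward the fragment containing the smallest original atom
    index, so the result is stable under input ordering.
    """
    comps = _components(mol.bonds)
    if len(comps) == 1:
        return mol

    def heavy_count(comp: list[int]) -> int:
        return sum(1 for i in comp if mol.atom_types[i] != "H")

    best = max(comps, key=lambda c: (heavy_count(c), -min(c)))
    idx = np.array(sorted(best), dtype=int)
    return Molecule3D(
        [mol.atom_types[i] for i in idx],
        mol.positions[idx],
        mol.bonds[np.ix_(idx, idx)],
        name=mol.name,
    )
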