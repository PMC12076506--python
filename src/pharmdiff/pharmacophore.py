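"""Pharmacophore extraction, constraint specification, and satisfaction tests.

A pharmacophore point is a fixed 3D position with a feature family (hydrogen
bond donor or acceptor here; the vocabulary is extensible).  Points extracted
from a reference ligand sit on the matched feature atoms.  A
``ConstraintSpec`` binds the points to generated-atom slots through a binary
mask: masked slot k is permanently bound to point k for the whole sampling
trajectory.  A generated pose satisfies a point when some atom of matching
family lies within ``tau`` (default 1.0 Angstrom) of the point.

Donor/acceptor typing uses SMARTS patterns shipped as a versioned data file
(``data/feature_smarts.json``) mirroring the default RDKit feature
definitions, so results do not drift with toolkit versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from .errors import CapacityError, ConfigError, SchemaError
from .molio import Molecule3D, to_rdkit


@lru_cache(maxsize=1)
def _family_patterns() -> dict[str, list[Chem.Mol]]:
    raw = json.loads(
        resources.files("pharmdiff").joinpath("data/feature_smarts.json").read_text()
    )
    out: dict[str, list[Chem.Mol]] = {}
    for fam, patterns in raw["families"].items():
        mols = []
        for smarts in patterns:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ConfigError(f"bad SMARTS for family {fam!r}: {smarts}")
            mols.append(q)
        out[fam] = mols
    return out


def known_families() -> set[str]:
    return set(_family_patterns())


@dataclass
class PharmacophorePoint:
    """A fixed feature position: 3-vector (Angstrom) plus feature family."""

    position: np.ndarray
    family: str
    source_atom_index: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("pharmacophore position must be finite")
        if self.family not in known_families():
            raise ConfigError(f"unknown pharmacophore family {self.family!r}")


@dataclass
class ConstraintSpec:
    """Pharmacophore constraints bound to generated-atom slots.

    ``mask`` has one True entry per point; masked slot k is bound to
    ``points[k]``.  ``fixed_atom_types``, if given, clamps the element of each
    masked slot every step.  ``tau`` is the satisfaction distance threshold.
    """

    points: list[PharmacophorePoint] = field(default_factory=list)
    mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    fixed_atom_types: list[str] | None = None
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != len(self.points):
            raise ValueError("number of mask ones must equal number of points")
        if self.fixed_atom_types is not None and len(self.fixed_atom_types) != len(self.points):
            raise ValueError("fixed_atom_types must align with points")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def masked_slots(self) -> np.ndarray:
        """Slot indices bound to points, in point order."""
        return np.flatnonzero(self.mask)

    def point_positions(self) -> np.ndarray:
        if not self.points:
            return np.zeros((0, 3))
        return np.stack([p.position for p in self.points])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ConstraintSpec":
        pts = [
            PharmacophorePoint(
                np.asarray(rotation) @ p.position + np.asarray(translation),
                p.family, p.source_atom_index)
            for p in self.points
        ]
        return ConstraintSpec(pts, self.mask.copy(), self.fixed_atom_types, self.tau)


def feature_atoms(rdmol: Chem.Mol, family: str) -> set[int]:
    """Indices of heavy atoms of ``rdmol`` matching the family's SMARTS set."""
    patterns = _family_patterns()
    if family not in patterns:
        raise ConfigError(f"unknown pharmacophore family {family!r}")
    hits: set[int] = set()
    for q in patterns[family]:
        for match in rdmol.GetSubstructMatches(q):
            hits.update(match)
    return hits


def extract_pharmacophores(
    ref: Molecule3D, families: set[str] | None = None
) -> list[PharmacophorePoint]:
    """One point per matched donor/acceptor atom, at that atom's coordinates.

    An atom matching several families yields one point per family (a hydroxyl
    oxygen is both donor and acceptor).  Points are ordered by family name,
    then atom index.
    """
    families = set(families) if families is not None else {"donor", "acceptor"}
    unknown = families - known_families()
    if unknown:
        raise ConfigError(f"unknown pharmacophore families: {sorted(unknown)}")
    rdmol = to_rdkit(ref, sanitize=True)
    points = []
    for fam in sorted(families):
        for idx in sorted(feature_atoms(rdmol, fam)):
            points.append(
                PharmacophorePoint(ref.positions[idx], fam, source_atom_index=idx))
    return points


def build_constraints(
    points: list[PharmacophorePoint],
    fixed_types: list[str] | None = None,
    tau: float = 1.0,
    slots: int = 0,
) -> ConstraintSpec:
    """Bind points to the first ``len(points)`` of ``slots`` atom slots."""
    if len(points) > slots:
        raise CapacityError(
            f"{len(points)} pharmacophore points exceed {slots} atom slots")
    mask = np.zeros(slots, dtype=bool)
    mask[: len(points)] = True
    return ConstraintSpec(list(points), mask, fixed_types, tau)


def reference_bound_constraints(
    ref: Molecule3D,
    families: set[str] | None = None,
    tau: float = 1.0,
    fix_types: bool = False,
) -> ConstraintSpec:
    """Constraints whose masked slots are the reference's own feature atoms.

    One point per feature atom (an atom matching several families contributes
    a single point; donor preferred), with the mask bit set at the source
    atom index — so the anchored atom is the one that natively carries the
    feature.  With ``fix_types`` the slot is also clamped to the source
    atom's element.
    """
    points = extract_pharmacophores(ref, families)
    by_atom: dict[int, PharmacophorePoint] = {}
    for p in sorted(points, key=lambda p: (p.family != "donor",)):
        by_atom.setdefault(p.source_atom_index, p)
    chosen = [by_atom[i] for i in sorted(by_atom)]
    mask = np.zeros(ref.n_atoms, dtype=bool)
    for p in chosen:
        mask[p.source_atom_index] = True
    fixed = [ref.atom_types[p.source_atom_index] for p in chosen] if fix_types else None
    return ConstraintSpec(chosen, mask, fixed, tau)


def satisfaction(
    mol: Molecule3D, spec: ConstraintSpec, strict: bool = False
) -> tuple[bool, list[dict]]:
    """Check whether ``mol`` fulfills every pharmacophore point of ``spec``.

    A point is satisfied iff some atom of ``mol`` lies within ``spec.tau`` of
    the point position AND that atom matches the point's family (SMARTS typing
    applied to ``mol``).  With ``strict=True`` only the atom occupying the
    slot bound to the point may satisfy it.

    Returns (overall verdict, per-point report); the report lists the nearest
    matching-family distance per point (inf when no atom matches the family).
    """
    fam_atoms: dict[str, set[int]] = {}
    try:
        rdmol = to_rdkit(mol, sanitize=True)
        for fam in {p.family for p in spec.points}:
            fam_atoms[fam] = feature_atoms(rdmol, fam)
    except Chem.rdchem.MolSanitizeException:
        fam_atoms = {p.family: set() for p in spec.points}

    slots = spec.masked_slots
    report = []
    all_ok = True
    for k, point in enumerate(spec.points):
        candidates = fam_atoms.get(point.family, set())
        if strict:
            candidates = candidates & {int(slots[k])} if k < len(slots) else set()
        if candidates:
            idx = np.array(sorted(candidates), dtype=int)
            dists = np.linalg.norm(mol.positions[idx] - point.position, axis=1)
            nearest = float(dists.min())
            nearest_atom = int(idx[int(dists.argmin())])
        else:
            nearest, nearest_atom = float("inf"), None
        ok = nearest <= spec.tau
        all_ok &= ok
        report.append({
            "point": k,
            "family": point.family,
            "nearest_matching_distance": nearest,
            "nearest_atom": nearest_atom,
            "satisfied": bool(ok),
        })
    return bool(all_ok), report


# ---------------------------------------------------------------------------
# JSON round-trip

def write_pharm_json(spec_or_points, path: str | Path, tau: float | None = None) -> None:
    """Write a pharmacophore JSON document.

    Accepts either a ConstraintSpec or a list of PharmacophorePoint.
    """
    if isinstance(spec_or_points, ConstraintSpec):
        points = spec_or_points.points
        fixed = spec_or_points.fixed_atom_types
        tau = spec_or_points.tau if tau is None else tau
    else:
        points, fixed = list(spec_or_points), None
        tau = 1.0 if tau is None else tau
    doc = {"tau": tau, "points": []}
    for k, p in enumerate(points):
        entry: dict = {"xyz": [float(x) for x in p.position], "family": p.family}
        if fixed is not None:
            entry["fixed_element"] = fixed[k]
        doc["points"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_pharm_json(path: str | Path) -> tuple[list[PharmacophorePoint], list[str] | None, float]:
    """Strictly parse a pharmacophore JSON document.

    Returns (points, fixed_elements or None, tau).  Raises
    :class:`SchemaError` on any structural problem.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read pharmacophore JSON {path}: {exc}") from exc
    if not isinstance(doc, dict) or "points" not in doc:
        raise SchemaError("pharmacophore JSON must be an object with a 'points' list")
    tau = doc.get("tau", 1.0)
    if not isinstance(tau, (int, float)) or not tau > 0:
        raise SchemaError("tau must be a positive number")
    if not isinstance(doc["points"], list):
        raise SchemaError("'points' must be a list")
    points: list[PharmacophorePoint] = []
    fixed: list[str] = []
    any_fixed = False
    for i, entry in enumerate(doc["points"]):
        if not isinstance(entry, dict):
            raise SchemaError(f"point {i} is not an object")
        extra = set(entry) - {"xyz", "family", "fixed_element"}
        if extra:
            raise SchemaError(f"point {i} has unknown keys {sorted(extra)}")
        xyz = entry.get("xyz")
        if (not isinstance(xyz, list) or len(xyz) != 3
                or not all(isinstance(x, (int, float)) for x in xyz)):
            raise SchemaError(f"point {i}: 'xyz' must be three numbers")
        fam = entry.get("family")
        if fam not in known_families():
            raise SchemaError(f"point {i}: unknown family {fam!r}")
        points.append(PharmacophorePoint(np.array(xyz, dtype=float), fam))
        fe = entry.get("fixed_element")
        if fe is not None:
            if not isinstance(fe, str):
                raise SchemaError(f"point {i}: fixed_element must be a string")
            any_fixed = True
        fixed.append(fe if fe is not None else "")
    if any_fixed and any(f == "" for f in fixed):
        raise SchemaError("either all points or none may carry fixed_element")
    return points, (fixed if any_fixed else None), float(tau)
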