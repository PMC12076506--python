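"""Closed-form toy denoiser and synthetic pocket/ligand fixtures.

The toy system stands in for a trained 3D molecular diffusion model so the
whole conditioning loop and metric suite run in seconds with no weights:

* the **template** is a random tree-bonded heavy-atom molecule (vocabulary
  C/N/O, single bonds) guaranteed to carry at least one hydrogen-bond donor
  (an amine N) and one acceptor (a hydroxyl O);
* the **pocket** is a spherical shell of protein-like points with an opening
  cap, enclosing the template with clearance above the clash threshold;
* the **denoiser** knows the template exactly and returns the closed-form
  Gaussian posterior mean of the forward process
  ``q(r_t | r_0) = Normal(sqrt(abar_t) r_0, (1 - abar_t) I)`` — computed
  about the template centroid so the chain is exactly E(3)-equivariant —
  with one-hot type/bond logits.

Unconditional sampling therefore reconstructs the template up to the residual
step noise, which makes every conditioning effect measurable against a known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import GenerationError, StepError
from .guidance import DenoiserOutput, ScheduleSpec
from .molio import Molecule3D, ProteinContext, write_ligands, write_protein
from .pharmacophore import extract_pharmacophores, write_pharm_json

TOY_VOCABULARY: tuple[str, ...] = ("C", "N", "O")
TOY_BOND_STATES = 2  # none / single

_BOND_LENGTH = 1.5          # Angstrom, tree edges
_MIN_SEPARATION = 1.2       # Angstrom, nonbonded template atoms


def toy_schedule(T: int = 50) -> ScheduleSpec:
    """Default toy schedule: T = 50 steps, beta linear 1e-4 -> 0.1."""
    return ScheduleSpec(T=T, beta=np.linspace(1e-4, 0.1, T))


class ToyDenoiser:
    """Analytic denoiser pinned to a known template molecule.

    ``denoise`` returns the exact DDPM posterior mean of ``r_{t-1}`` given
    ``r_t`` and ``r_0 = template``, computed on centroid-centered coordinates:

        mu = c + c1 * (r0 - c) + c2 * (r_t - c),
        c1 = sqrt(abar_{t-1}) beta_t / (1 - abar_t),
        c2 = sqrt(alpha_t) (1 - abar_{t-1}) / (1 - abar_t),

    with c the template centroid.  Type and bond logits are one-hot encodings
    of the template, so the modal category reproduces its graph exactly.
    """

    def __init__(self, template: Molecule3D, sched: ScheduleSpec | None = None,
                 vocabulary: tuple[str, ...] = TOY_VOCABULARY):
        self.template = template
        self._sched = sched if sched is not None else toy_schedule()
        self._vocab = vocabulary
        unknown = set(template.atom_types) - set(vocabulary)
        if unknown:
            raise ValueError(f"template elements outside vocabulary: {unknown}")
        n = template.n_atoms
        k = len(vocabulary)
        self._type_logits = np.full((n, k), -1e3)
        for i, sym in enumerate(template.atom_types):
            self._type_logits[i, vocabulary.index(sym)] = 0.0
        self._bond_logits = np.full((n, n, TOY_BOND_STATES), -1e3)
        single = np.clip(template.bonds, 0, 1)
        for s in range(TOY_BOND_STATES):
            self._bond_logits[:, :, s] = np.where(single == s, 0.0, -1e3)

    def vocabulary(self) -> tuple[str, ...]:
        return self._vocab

    def schedule(self) -> ScheduleSpec:
        return self._sched

    def denoise(self, positions: np.ndarray, types: np.ndarray,
                bonds: np.ndarray, t: int) -> DenoiserOutput:
        sched = self._sched
        if not 1 <= t <= sched.T:
            raise StepError(f"step t={t} outside [1, {sched.T}]")
        beta_t = sched.beta_t(t)
        ab_t = sched.alpha_bar_t(t)
        ab_prev = sched.alpha_bar_t(t - 1)
        denom = 1.0 - ab_t
        c1 = math.sqrt(ab_prev) * beta_t / denom
        c2 = math.sqrt(1.0 - beta_t) * (1.0 - ab_prev) / denom
        c = self.template.centroid()
        mu = c + c1 * (self.template.positions - c) + c2 * (np.asarray(positions) - c)
        return DenoiserOutput(
            mu=mu,
            type_logits=self._type_logits.copy(),
            bond_logits=self._bond_logits.copy(),
            sigma_sq_t=sched.sigma_sq_t(t),
        )


@dataclass
class ToySystem:
    """A synthetic complex: template ligand, shell pocket, donor/acceptor
    subset of the template atoms, and the toy schedule."""

    template: Molecule3D
    pocket: ProteinContext
    pharm_subset: list[int]
    sched: ScheduleSpec

    def denoiser(self) -> ToyDenoiser:
        return ToyDenoiser(self.template, self.sched)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ToySystem":
        return ToySystem(
            template=self.template.transformed(rotation, translation),
            pocket=self.pocket.transformed(rotation, translation),
            pharm_subset=list(self.pharm_subset),
            sched=self.sched,
        )


def _grow_tree(rng: np.random.Generator, n_atoms: int, r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Grow a tree-bonded heavy-atom skeleton inside a ball of radius r_max."""
    pos = np.zeros((n_atoms, 3))
    bonds = np.zeros((n_atoms, n_atoms), dtype=int)
    pos[0] = rng.normal(scale=0.3, size=3)
    degree = np.zeros(n_atoms, dtype=int)
    for i in range(1, n_atoms):
        for _ in range(100):
            parent = int(rng.integers(0, i))
            if degree[parent] >= 4:  # keep carbon valence satisfiable
                continue
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = pos[parent] + _BOND_LENGTH * direction
            if np.linalg.norm(cand) > r_max:
                continue
            others = np.delete(np.arange(i), parent)
            if len(others) and np.min(np.linalg.norm(pos[others] - cand, axis=1)) < _MIN_SEPARATION:
                continue
            pos[i] = cand
            bonds[i, parent] = bonds[parent, i] = 1
            degree[i] += 1
            degree[parent] += 1
            break
        else:
            raise GenerationError("could not place template atom after 100 rejections")
    return pos, bonds


def make_toy_complex(
    seed: int,
    n_atoms: int = 12,
    pocket_radius: float = 8.0,
    n_pocket_atoms: int = 200,
) -> ToySystem:
    """Build a deterministic synthetic protein-ligand complex.

    The template (>= 4 heavy atoms) is centered in a shell pocket of radius
    ``pocket_radius`` (> 3 Angstrom) with a polar opening cap; every template
    atom keeps a surface clearance above the pocket's clash threshold.  Two
    leaf atoms are typed O (hydroxyl: donor + acceptor) and N (amine: donor),
    the rest C.  Pocket points are mostly carbon with O/N sprinkled in so
    protein-side hydrogen-bond partners exist.
    """
    if n_atoms < 4:
        raise ValueError("n_atoms must be >= 4")
    if not pocket_radius > 3.0:
        raise ValueError("pocket_radius must be > 3 Angstrom")
    rng = np.random.default_rng(seed)
    clash_threshold = 2.0
    # The soft-min surface sits below the true minimum distance, so the
    # template needs clearance well beyond the clash threshold itself.
    r_max = pocket_radius - clash_threshold - 2.0
    if r_max <= _BOND_LENGTH:
        raise GenerationError("pocket too small for the template")

    for _ in range(100):
        pos, bonds = _grow_tree(rng, n_atoms, r_max)
        pos = pos - pos.mean(axis=0)
        if np.max(np.linalg.norm(pos, axis=1)) <= r_max:
            break
    else:
        raise GenerationError("could not center template inside pocket")

    degree = (bonds != 0).sum(axis=1)
    leaves = [i for i in range(n_atoms) if degree[i] == 1]
    if len(leaves) < 2:
        raise GenerationError("tree has fewer than two leaves")
    types = ["C"] * n_atoms
    types[leaves[-1]] = "O"   # hydroxyl-like leaf: donor + acceptor
    types[leaves[0]] = "N"    # amine-like leaf: donor (and acceptor)
    template = Molecule3D(types, pos, bonds, name=f"toy-template-{seed}")

    # Shell pocket with an opening cap around +z.
    shell = []
    elements = []
    labels = []
    i = 0
    while len(shell) < n_pocket_atoms:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[2] > 0.7:  # opening
            continue
        shell.append(pocket_radius * v)
        elements.append("O" if i % 7 == 3 else ("N" if i % 11 == 5 else "C"))
        labels.append(f"A:POC:{i + 1}")
        i += 1
    pocket = ProteinContext(np.array(shell), labels, elements,
                            sigma=0.5, clash_threshold=clash_threshold)

    from .guidance import protein_surface  # local import avoids cycle at module load
    clearance = np.asarray(protein_surface(template.positions, pocket))
    if np.any(clearance <= clash_threshold):
        raise GenerationError("template violates pocket clearance")

    points = extract_pharmacophores(template)
    fams = {p.family for p in points}
    if not {"donor", "acceptor"} <= fams:
        raise GenerationError("template lacks a donor or an acceptor")
    pharm_subset = sorted({p.source_atom_index for p in points})

    return ToySystem(template, pocket, pharm_subset, toy_schedule())


def hbond_probe_context(system: ToySystem, probe_distance: float = 2.9) -> ProteinContext:
    """Pocket augmented with H-bond probe atoms near the template's features.

    The toy pocket shell is built with clearance beyond hydrogen-bonding
    range, so the bare system forms no protein-ligand H-bonds.  This helper
    adds, per template donor, a protein acceptor O on the extended D-H axis
    at ``probe_distance`` from the donor heavy atom, and per template
    acceptor, a protein donor N at ``probe_distance`` radially outward — each
    as its own labeled residue — giving the interaction-similarity metric a
    non-empty reference bond set.
    """
    from rdkit import Chem

    from .molio import to_rdkit

    rdmol = Chem.AddHs(to_rdkit(system.template), addCoords=True)
    pos = np.array(rdmol.GetConformer().GetPositions())
    points = extract_pharmacophores(system.template)
    probes, elements, labels = [], [], []
    n_existing = system.pocket.n_atoms
    for k, p in enumerate(points):
        i = p.source_atom_index
        if p.family == "donor":
            hs = [n.GetIdx() for n in rdmol.GetAtomWithIdx(i).GetNeighbors()
                  if n.GetSymbol() == "H"]
            if not hs:
                continue
            direction = pos[hs[0]] - pos[i]
            direction /= np.linalg.norm(direction)
            probes.append(pos[i] + probe_distance * direction)
            elements.append("O")
        else:
            center = system.template.positions.mean(axis=0)
            direction = pos[i] - center
            direction /= max(np.linalg.norm(direction), 1e-9)
            probes.append(pos[i] + probe_distance * direction)
            elements.append("N")
        labels.append(f"B:PRB:{n_existing + k + 1}")
    return ProteinContext(
        np.vstack([system.pocket.atom_positions, np.array(probes)]),
        list(system.pocket.residue_labels) + labels,
        list(system.pocket.elements) + elements,
        sigma=system.pocket.sigma,
        clash_threshold=system.pocket.clash_threshold,
    )


def write_complex(system: ToySystem, outdir: str | Path) -> dict[str, Path]:
    """Write template.sdf, pocket.pdb and pharm.json for CLI-level tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "template": outdir / "template.sdf",
        "pocket": outdir / "pocket.pdb",
        "pocket_probes": outdir / "pocket_probes.pdb",
        "pharm": outdir / "pharm.json",
    }
    write_ligands(system.template, paths["template"])
    write_protein(system.pocket, paths["pocket"])
    # variant with H-bond probe atoms, for interaction-similarity evaluation
    write_protein(hbond_probe_context(system), paths["pocket_probes"])
    write_pharm_json(extract_pharmacophores(system.template), paths["pharm"])
    return paths
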