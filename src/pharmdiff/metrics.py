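"""Evaluation suite for generated poses.

Covers geometric hydrogen-bond detection and interaction similarity,
shape-and-color 3D similarity (poses compared in place, no realignment),
Ertl synthetic-accessibility and QED drug-likeness scoring, fingerprint
diversity, docking-score normalization, structural alert filters, per-pocket
success rates, and top-k selection by shape-and-color score.
"""

from __future__ import annotations

import gzip
import math
import pickle
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem, DataStructs, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures, QED, rdMolDescriptors
from rdkit.Chem.FeatMaps import FeatMaps
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .errors import ConfigError, UndefinedMetricError
from .molio import Molecule3D, ProteinContext, to_rdkit
from .pharmacophore import feature_atoms


@dataclass
class MetricConfig:
    """Tunable constants of the metric suite.

    H-bond geometry: heavy-atom donor-acceptor distance cutoff (Angstrom) and
    minimum D-H...A angle (degrees).  Fingerprints: Morgan radius 2, 2048
    bits.  ``sc_weights`` mixes shape and color similarity (must sum to 1).
    """

    hbond_dist_max: float = 3.5
    hbond_angle_min: float = 120.0
    fp_radius: int = 2
    fp_bits: int = 2048
    qed_threshold: float = 0.19
    sa_threshold: float = 0.33
    sc_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0 < self.hbond_dist_max < 10:
            raise ConfigError("hbond_dist_max out of range")
        if not 0 <= self.hbond_angle_min <= 180:
            raise ConfigError("hbond_angle_min out of range")
        if self.fp_bits & (self.fp_bits - 1):
            raise ConfigError("fp_bits must be a power of two")
        if abs(sum(self.sc_weights) - 1.0) > 1e-9:
            raise ConfigError("sc_weights must sum to 1")


DEFAULT_CONFIG = MetricConfig()


# ---------------------------------------------------------------------------
# Hydrogen bonds

@dataclass
class HBond:
    """One detected protein-ligand hydrogen bond (heavy-atom geometry)."""

    protein_residue: str
    ligand_role: str            # "donor" or "acceptor"
    donor_pos: np.ndarray
    acceptor_pos: np.ndarray
    distance: float

    def __post_init__(self) -> None:
        if self.ligand_role not in ("donor", "acceptor"):
            raise ValueError("ligand_role must be 'donor' or 'acceptor'")
        if not self.distance > 0:
            raise ValueError("distance must be > 0")


def _protonated(lig: Molecule3D) -> Chem.Mol:
    rdmol = to_rdkit(lig, sanitize=True)
    return Chem.AddHs(rdmol, addCoords=True)


def detect_hbonds(
    lig: Molecule3D, ctx: ProteinContext, config: MetricConfig = DEFAULT_CONFIG
) -> list[HBond]:
    """Geometric protein-ligand hydrogen bond scan.

    Ligand hydrogens are added internally (coordinates inferred) if absent.
    Ligand-donor direction: donor heavy atom D with an attached H such that
    dist(D, A_protein) <= cutoff and angle(D-H...A) >= angle_min; protein
    acceptors are O atoms.  Ligand-acceptor direction: protein N donors
    paired with ligand acceptor atoms on the distance criterion (protein
    protons are not present in heavy-atom contexts, so no angle is imposed
    on the protein side).
    """
    rdmol = _protonated(lig)
    conf = rdmol.GetConformer()
    pos = np.array(conf.GetPositions(), dtype=float)
    heavy_donors = feature_atoms(rdmol, "donor")
    heavy_acceptors = feature_atoms(rdmol, "acceptor")
    ppos = ctx.atom_positions
    out: list[HBond] = []
    angle_min = math.radians(config.hbond_angle_min)

    prot_acc = [j for j, e in enumerate(ctx.elements) if e == "O"]
    prot_don = [j for j, e in enumerate(ctx.elements) if e == "N"]

    for d_idx in sorted(heavy_donors):
        h_idx = [n.GetIdx() for n in rdmol.GetAtomWithIdx(d_idx).GetNeighbors()
                 if n.GetSymbol() == "H"]
        if not h_idx:
            continue
        for j in prot_acc:
            dist = float(np.linalg.norm(pos[d_idx] - ppos[j]))
            if dist > config.hbond_dist_max:
                continue
            for h in h_idx:
                v1 = pos[d_idx] - pos[h]
                v2 = ppos[j] - pos[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if math.acos(np.clip(cosang, -1.0, 1.0)) >= angle_min:
                    out.append(HBond(ctx.residue_labels[j], "donor",
                                     pos[d_idx].copy(), ppos[j].copy(), dist))
                    break

    for a_idx in sorted(heavy_acceptors):
        for j in prot_don:
            dist = float(np.linalg.norm(pos[a_idx] - ppos[j]))
            if dist <= config.hbond_dist_max:
                out.append(HBond(ctx.residue_labels[j], "acceptor",
                                 ppos[j].copy(), pos[a_idx].copy(), dist))
    return out


def _hbond_keys(bonds: list[HBond]) -> set[tuple[str, str]]:
    return {(b.protein_residue, b.ligand_role) for b in bonds}


def interaction_similarity(
    gen: Molecule3D, ref: Molecule3D, ctx: ProteinContext,
    config: MetricConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of the reference's hydrogen bonds the generated pose shares.

    A bond is shared when the generated ligand forms a bond to the same
    protein residue in the same ligand role; the score is capped at 1.
    """
    ref_keys = _hbond_keys(detect_hbonds(ref, ctx, config))
    if not ref_keys:
        raise UndefinedMetricError("reference ligand forms no hydrogen bonds")
    gen_keys = _hbond_keys(detect_hbonds(gen, ctx, config))
    return len(ref_keys & gen_keys) / len(ref_keys)


# ---------------------------------------------------------------------------
# Shape and color similarity

_FEATMAP_FAMILIES = ("Donor", "Acceptor", "NegIonizable", "PosIonizable",
                     "ZnBinder", "Aromatic", "Hydrophobe", "LumpedHydrophobe")


@lru_cache(maxsize=1)
def _feature_factory() -> ChemicalFeatures.MolChemicalFeatureFactory:
    import os
    return ChemicalFeatures.BuildFeatureFactory(
        os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef"))


def _featmap_feats(rdmol: Chem.Mol):
    return [f for f in _feature_factory().GetFeaturesForMol(rdmol)
            if f.GetFamily() in _FEATMAP_FAMILIES]


def _color_similarity(gen_rd: Chem.Mol, ref_rd: Chem.Mol) -> float:
    ref_feats = _featmap_feats(ref_rd)
    gen_feats = _featmap_feats(gen_rd)
    if not ref_feats and not gen_feats:
        return 1.0  # vacuously identical pharmacophoric content
    if not ref_feats or not gen_feats:
        return 0.0
    params = {fam: FeatMaps.FeatMapParams() for fam in _FEATMAP_FAMILIES}
    fm = FeatMaps.FeatMap(feats=ref_feats, weights=[1.0] * len(ref_feats),
                          params=params)
    fm.scoreMode = FeatMaps.FeatMapScoreMode.Best
    score = fm.ScoreFeats(gen_feats) / min(fm.GetNumFeatures(), len(gen_feats))
    return float(np.clip(score, 0.0, 1.0))


def shape_color_similarity(
    gen: Molecule3D, ref: Molecule3D, config: MetricConfig = DEFAULT_CONFIG
) -> float:
    """Mean of volumetric shape overlap and pharmacophoric-feature overlap.

    Both terms lie in [0, 1]; poses are compared in their given frames
    without realignment.
    """
    gen_rd = to_rdkit(gen, sanitize=True)
    ref_rd = to_rdkit(ref, sanitize=True)
    shape = 1.0 - AllChem.ShapeTanimotoDist(gen_rd, ref_rd)
    color = _color_similarity(gen_rd, ref_rd)
    w_shape, w_color = config.sc_weights
    return float(np.clip(w_shape * shape + w_color * color, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Synthetic accessibility (Ertl fragment-contribution score)

@lru_cache(maxsize=1)
def _fragment_scores() -> dict[int, float]:
    """Fragment-frequency contribution table (loaded from the installed
    toolkit's published data)."""
    import os
    path = os.path.join(RDConfig.RDContribDir, "SA_Score", "fpscores.pkl.gz")
    with gzip.open(path, "rb") as fh:
        data = pickle.load(fh)
    out: dict[int, float] = {}
    for row in data:
        for bit in row[1:]:
            out[bit] = float(row[0])
    return out


def sa_score_raw(mol: Molecule3D | Chem.Mol) -> float:
    """Ertl synthetic-accessibility score on the raw 1 (easy) .. 10 (hard) scale.

    Fragment contributions from a historical fragment-frequency table plus
    complexity penalties for size, stereocenters, spiro and bridgehead atoms,
    and macrocycles, with the published symmetry correction and 8..10
    smoothing.
    """
    from rdkit.Chem import rdFingerprintGenerator

    rdmol = mol if isinstance(mol, Chem.Mol) else to_rdkit(mol, sanitize=True)
    scores = _fragment_scores()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
    elements = gen.GetSparseCountFingerprint(rdmol).GetNonzeroElements()
    frag_score, n_frag = 0.0, 0
    for bit, count in elements.items():
        n_frag += count
        frag_score += scores.get(bit, -4.0) * count
    frag_score /= max(n_frag, 1)

    n_atoms = rdmol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(rdmol, includeUnassigned=True))
    ri = rdmol.GetRingInfo()
    n_macro = sum(1 for ring in ri.AtomRings() if len(ring) > 8)
    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(rdMolDescriptors.CalcNumSpiroAtoms(rdmol) + 1)
    bridge_penalty = math.log10(rdMolDescriptors.CalcNumBridgeheadAtoms(rdmol) + 1)
    macro_penalty = math.log10(2) if n_macro > 0 else 0.0
    complexity = (-size_penalty - stereo_penalty - spiro_penalty
                  - bridge_penalty - macro_penalty)

    # correction for symmetric molecules with few distinct fragments
    correction = 0.0
    if n_atoms > len(elements):
        correction = math.log(float(n_atoms) / len(elements)) * 0.5

    sascore = frag_score + complexity + correction
    lo, hi = -4.0, 2.5
    sascore = 11.0 - (sascore - lo + 1.0) / (hi - lo) * 9.0
    if sascore > 8.0:
        sascore = 8.0 + math.log(sascore + 1.0 - 9.0)
    return float(np.clip(sascore, 1.0, 10.0))


def sa_score_normalized(mol: Molecule3D | Chem.Mol) -> float:
    """SA mapped to [0, 1] with high = easier to synthesize: (10 - raw) / 9."""
    return (10.0 - sa_score_raw(mol)) / 9.0


# ---------------------------------------------------------------------------
# Drug-likeness, diversity, docking normalization

def qed(mol: Molecule3D | Chem.Mol) -> float:
    """Quantitative estimate of drug-likeness (weighted-desirability
    geometric mean over the eight standard properties)."""
    rdmol = mol if isinstance(mol, Chem.Mol) else to_rdkit(mol, sanitize=True)
    return float(QED.qed(rdmol))


def _morgan_fp(rdmol: Chem.Mol, config: MetricConfig):
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.fp_radius, fpSize=config.fp_bits)
    return gen.GetFingerprint(rdmol)


def diversity(mols: list[Molecule3D | Chem.Mol],
              config: MetricConfig = DEFAULT_CONFIG) -> float:
    """1 - mean pairwise Tanimoto similarity of Morgan fingerprints."""
    if len(mols) < 2:
        raise UndefinedMetricError("diversity needs at least two molecules")
    fps = [_morgan_fp(m if isinstance(m, Chem.Mol) else to_rdkit(m), config)
           for m in mols]
    sims = [DataStructs.TanimotoSimilarity(fps[i], fps[j])
            for i in range(len(fps)) for j in range(i + 1, len(fps))]
    return 1.0 - float(np.mean(sims))


def normalized_score(score: float, n_atoms: int) -> float:
    """Deflate a docking score's size bias: score / sqrt(n_atoms)."""
    if n_atoms <= 0:
        raise ValueError("n_atoms must be >= 1")
    return score / math.sqrt(n_atoms)


# ---------------------------------------------------------------------------
# Structural filters and success rate

_CATALOG_ENUM = {
    "NIH": FilterCatalogParams.FilterCatalogs.NIH,
    "PAINS": FilterCatalogParams.FilterCatalogs.PAINS,
    "Brenk": FilterCatalogParams.FilterCatalogs.BRENK,
}


@lru_cache(maxsize=None)
def _catalog(names: tuple[str, ...]) -> FilterCatalog:
    params = FilterCatalogParams()
    for name in names:
        params.AddCatalog(_CATALOG_ENUM[name])
    return FilterCatalog(params)


def structural_filters(
    mol: Molecule3D | Chem.Mol, catalogs: set[str] = frozenset({"NIH"})
) -> tuple[bool, list[str]]:
    """Screen against structural-alert catalogs (NIH / PAINS / Brenk).

    Returns (pass, hit names); passes iff no catalog pattern matches.
    """
    unknown = set(catalogs) - set(_CATALOG_ENUM)
    if unknown:
        raise ConfigError(f"unknown filter catalogs: {sorted(unknown)}")
    if not catalogs:
        return True, []
    rdmol = mol if isinstance(mol, Chem.Mol) else to_rdkit(mol, sanitize=True)
    matches = _catalog(tuple(sorted(catalogs))).GetMatches(rdmol)
    hits = [m.GetDescription() for m in matches]
    return len(hits) == 0, hits


def success_rate(
    mols_per_pocket: dict[str, list[Molecule3D | Chem.Mol]],
    qed_min: float = 0.19,
    sa_min: float = 0.33,
    validity_flags: dict[str, list[bool]] | None = None,
) -> tuple[dict[str, float], int]:
    """Per-pocket fraction of viable molecules, plus the empty-pocket count.

    A molecule counts as a success when it is validity-flagged true (all-true
    offline), passes the NIH structural filter, and meets the QED and
    normalized-SA thresholds.  Pockets with zero passers are tallied in the
    second return value.
    """
    rates: dict[str, float] = {}
    n_empty = 0
    for pocket, mols in mols_per_pocket.items():
        flags = (validity_flags or {}).get(pocket, [True] * len(mols))
        if len(flags) != len(mols):
            raise ValueError(f"validity flags misaligned for pocket {pocket!r}")
        n_pass = 0
        for mol, valid in zip(mols, flags):
            if not valid:
                continue
            ok_filter, _ = structural_filters(mol, {"NIH"})
            if not ok_filter:
                continue
            if qed(mol) >= qed_min and sa_score_normalized(mol) >= sa_min:
                n_pass += 1
        rates[pocket] = n_pass / len(mols) if mols else 0.0
        if n_pass == 0:
            n_empty += 1
    return rates, n_empty


# ---------------------------------------------------------------------------
# Top-k selection

def topk_by_sc(
    mols: list[Molecule3D],
    ref: Molecule3D,
    k: int,
    config: MetricConfig = DEFAULT_CONFIG,
) -> list[Molecule3D]:
    """k molecules with the highest shape-and-color similarity to ``ref``.

    Descending order; ties keep input order (stable).  Downstream metrics
    are conventionally reported as the best value within this subset.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(mols):
        warnings.warn(f"k={k} exceeds {len(mols)} molecules; returning all",
                      stacklevel=2)
        k = len(mols)
    scores = np.array([shape_color_similarity(m, ref, config) for m in mols])
    order = np.argsort(-scores, kind="stable")
    return [mols[i] for i in order[:k]]
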