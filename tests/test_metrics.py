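import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from pharmdiff.errors import ConfigError, UndefinedMetricError
from pharmdiff.metrics import (
    DEFAULT_CONFIG,
    MetricConfig,
    detect_hbonds,
    diversity,
    interaction_similarity,
    normalized_score,
    qed,
    sa_score_normalized,
    sa_score_raw,
    shape_color_similarity,
    structural_filters,
    success_rate,
    topk_by_sc,
)
from pharmdiff.molio import Molecule3D, ProteinContext, from_rdkit, to_rdkit

from conftest import mol_from_smiles


def _renumbered(mol: Molecule3D, seed: int = 0) -> Molecule3D:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(mol.n_atoms)
    inv = np.argsort(perm)
    return Molecule3D(
        [mol.atom_types[i] for i in perm],
        mol.positions[perm],
        mol.bonds[np.ix_(perm, perm)],
    )


def _probe_ctx(positions, elements):
    positions = np.atleast_2d(positions)
    labels = [f"A:RES:{i+1}" for i in range(len(positions))]
    return ProteinContext(positions, labels, list(elements))


def _ligand_with_nh():
    """Methylamine with explicit hydrogens and known geometry."""
    return mol_from_smiles("CN", add_hs=True)


def _nh_geometry(lig):
    """Return (N position, one H-on-N position) from the embedded ligand."""
    rd = to_rdkit(lig)
    n_idx = next(a.GetIdx() for a in rd.GetAtoms() if a.GetSymbol() == "N")
    h_idx = next(n.GetIdx() for n in rd.GetAtomWithIdx(n_idx).GetNeighbors()
                 if n.GetSymbol() == "H")
    return n_idx, lig.positions[n_idx], lig.positions[h_idx]


class TestDetectHbonds:
    def test_linear_nh_o_pair_detected(self):
        lig = _ligand_with_nh()
        _, n_pos, h_pos = _nh_geometry(lig)
        u = (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)
        ctx = _probe_ctx(n_pos + 2.9 * u, ["O"])  # ~175 deg at H
        bonds = detect_hbonds(lig, ctx)
        assert len(bonds) == 1
        assert bonds[0].ligand_role == "donor"
        assert bonds[0].distance == pytest.approx(2.9)

    def test_beyond_distance_cutoff(self):
        lig = _ligand_with_nh()
        _, n_pos, h_pos = _nh_geometry(lig)
        u = (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)
        ctx = _probe_ctx(n_pos + 5.0 * u, ["O"])
        assert detect_hbonds(lig, ctx) == []

    def test_bad_donor_angle_rejected(self):
        lig = _ligand_with_nh()
        _, n_pos, h_pos = _nh_geometry(lig)
        u = (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)
        # build a probe at 2.9 A from N but at ~90 deg D-H...A angle
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        d_nh = np.linalg.norm(h_pos - n_pos)
        a = h_pos + perp * math.sqrt(max(2.9 ** 2 - d_nh ** 2, 0.1))
        ctx = _probe_ctx(a, ["O"])
        donor_bonds = [b for b in detect_hbonds(lig, ctx)
                       if b.ligand_role == "donor"]
        assert donor_bonds == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed, probe_context, toy_system):
        rng = np.random.default_rng(seed)
        lig = toy_system.template
        # jitter the ligand so distances and angles vary across cases
        jittered = Molecule3D(lig.atom_types,
                              lig.positions + rng.normal(0, 0.4, lig.positions.shape),
                              lig.bonds)
        got = {(b.protein_residue, b.ligand_role, round(b.distance, 6))
               for b in detect_hbonds(jittered, probe_context)}
        oracle = _hbond_oracle(jittered, probe_context)
        assert got == oracle


def _hbond_oracle(lig, ctx, config=DEFAULT_CONFIG):
    """Brute-force geometric scan re-deriving every criterion independently."""
    from pharmdiff.pharmacophore import feature_atoms

    rd = Chem.AddHs(to_rdkit(lig), addCoords=True)
    pos = np.array(rd.GetConformer().GetPositions())
    donors = feature_atoms(rd, "donor")
    acceptors = feature_atoms(rd, "acceptor")
    out = set()
    for d in donors:
        hs = [n.GetIdx() for n in rd.GetAtomWithIdx(d).GetNeighbors()
              if n.GetSymbol() == "H"]
        for j, e in enumerate(ctx.elements):
            if e != "O":
                continue
            a = ctx.atom_positions[j]
            dist = np.linalg.norm(pos[d] - a)
            if dist > config.hbond_dist_max:
                continue
            for h in hs:
                v1, v2 = pos[d] - pos[h], a - pos[h]
                ang = math.degrees(math.acos(np.clip(
                    np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2),
                    -1, 1)))
                if ang >= config.hbond_angle_min:
                    out.add((ctx.residue_labels[j], "donor", round(float(dist), 6)))
                    break
    for acc in acceptors:
        for j, e in enumerate(ctx.elements):
            if e != "N":
                continue
            dist = np.linalg.norm(pos[acc] - ctx.atom_positions[j])
            if dist <= config.hbond_dist_max:
                out.add((ctx.residue_labels[j], "acceptor", round(float(dist), 6)))
    return out


class TestInteractionSimilarity:
    def test_identity_is_one(self, toy_system, probe_context):
        t = toy_system.template
        assert interaction_similarity(t, t, probe_context) == 1.0

    def test_alkane_scores_zero(self, toy_system, probe_context):
        t = toy_system.template
        alkane = Molecule3D(["C"] * t.n_atoms, t.positions, t.bonds)
        assert interaction_similarity(alkane, t, probe_context) == 0.0

    def test_partial_recovery_is_fractional(self, toy_system, probe_context):
        t = toy_system.template
        # silence the hydroxyl oxygen: its donor and acceptor bonds vanish
        types = list(t.atom_types)
        types[types.index("O")] = "C"
        half = Molecule3D(types, t.positions, t.bonds)
        ref_keys = {(b.protein_residue, b.ligand_role)
                    for b in detect_hbonds(t, probe_context)}
        gen_keys = {(b.protein_residue, b.ligand_role)
                    for b in detect_hbonds(half, probe_context)}
        expected = len(ref_keys & gen_keys) / len(ref_keys)
        assert 0 < expected < 1
        assert interaction_similarity(half, t, probe_context) == expected

    def test_undefined_without_reference_bonds(self, toy_system):
        t = toy_system.template
        with pytest.raises(UndefinedMetricError):
            interaction_similarity(t, t, toy_system.pocket)  # bare shell: no bonds


class TestShapeColor:
    def test_self_similarity(self):
        mol = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        assert shape_color_similarity(mol, mol) >= 0.99

    def test_distant_molecules_do_not_overlap(self):
        mol = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        far = Molecule3D(mol.atom_types, mol.positions + [50.0, 0, 0], mol.bonds)
        assert shape_color_similarity(far, mol) <= 0.05

    def test_translation_decays_monotonically(self):
        mol = mol_from_smiles("c1ccncc1")
        self_sim = shape_color_similarity(mol, mol)
        shifted = Molecule3D(mol.atom_types, mol.positions + [1.0, 0, 0], mol.bonds)
        assert shape_color_similarity(shifted, mol) < self_sim


@pytest.fixture(scope="module")
def sascorer_oracle():
    import sys

    from rdkit import RDConfig
    sys.path.insert(0, f"{RDConfig.RDContribDir}/SA_Score")
    import sascorer
    return sascorer


class TestSyntheticAccessibility:
    @pytest.mark.parametrize("smiles", [
        "CC", "CCO", "c1ccccc1O", "CC(=O)Nc1ccc(O)cc1",
        "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "C1CCCCCCCCCC1",
        "C[C@H]1CC[C@@H](O)CC[C@H](N)CC[C@@H](F)CC1",
    ])
    def test_matches_reference_implementation(self, smiles, sascorer_oracle):
        mol = Chem.MolFromSmiles(smiles)
        assert sa_score_raw(mol) == pytest.approx(
            sascorer_oracle.calculateScore(mol), abs=1e-9)

    def test_simple_molecule_is_accessible(self, sascorer_oracle):
        eth = Chem.MolFromSmiles("CC")
        expected = (10.0 - sascorer_oracle.calculateScore(eth)) / 9.0
        assert sa_score_normalized(eth) == pytest.approx(expected)
        assert sa_score_normalized(eth) > 0.75

    def test_stereocenter_macrocycle_scores_lower_than_ethane(self):
        mac = Chem.MolFromSmiles("C[C@H]1CC[C@@H](O)CC[C@H](N)CC[C@@H](F)CC1")
        assert sa_score_normalized(mac) < sa_score_normalized(Chem.MolFromSmiles("CC"))

    def test_atom_order_invariance(self):
        mol = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        assert sa_score_normalized(mol) == pytest.approx(
            sa_score_normalized(_renumbered(mol, 3)), abs=1e-12)


class TestQed:
    def test_bounds_and_order_invariance(self):
        mol = mol_from_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O")
        v = qed(mol)
        assert 0 <= v <= 1
        assert v == pytest.approx(qed(_renumbered(mol, 1)), abs=1e-12)

    def test_matches_independent_desirability_evaluation(self):
        # published ADS coefficients (a, b, c, d, e, f, dmax) and weights
        ads_params = {
            "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353,
                   49.22325677, 65.37051707, 104.9805561),
            "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897,
                      0.822739154, 0.576295591, 131.3186604),
            "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202,
                    0.290141953, 1.300669958, 148.7763046),
            "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001,
                    0.713820843, 0.920922555, 258.1632616),
            "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614,
                    12.01999824, 28.51324732, 104.5686167),
            "ROTB": (0.010000000, 272.4121427, 2.558379970, 1.565547684,
                     1.271567166, 2.758063707, 105.4420403),
            "AROM": (3.217788970, 957.7374108, 2.274627939, 0.000000001,
                     1.317690384, 0.375760881, 312.3372610),
            "ALERTS": (0.010000000, 1199.094025, -0.09002883, 0.000000001,
                       0.185904477, 0.875193782, 417.7253140),
        }
        weights = {"MW": 0.66, "ALOGP": 0.46, "HBA": 0.05, "HBD": 0.61,
                   "PSA": 0.06, "ROTB": 0.65, "AROM": 0.48, "ALERTS": 0.95}

        def ads(x, p):
            a, b, c, d, e, f, dmax = p
            return (a + b / (1 + math.exp(-(x - c + d / 2) / e))
                    * (1 - 1 / (1 + math.exp(-(x - c - d / 2) / f)))) / dmax

        from rdkit.Chem import QED as rdqed
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
        props = rdqed.properties(mol)
        num = sum(w * math.log(ads(getattr(props, name), ads_params[name]))
                  for name, w in weights.items())
        oracle = math.exp(num / sum(weights.values()))
        assert qed(mol) == pytest.approx(oracle, abs=1e-6)


class TestDiversity:
    def test_identical_set_is_zero(self):
        mol = mol_from_smiles("CCO")
        assert diversity([mol, mol, mol]) == 0.0

    def test_disjoint_fingerprints_give_one(self):
        # heavy-atom graphs of ethane and benzene share no Morgan environment
        assert diversity([mol_from_smiles("CC", add_hs=False),
                          mol_from_smiles("c1ccccc1", add_hs=False)]) == 1.0

    def test_hand_enumerated_pair_average(self):
        a = mol_from_smiles("CC", add_hs=False)
        b = mol_from_smiles("CC", seed=11, add_hs=False)  # same fingerprint
        c = mol_from_smiles("c1ccccc1", add_hs=False)
        # pairwise sims {1, 0, 0} -> 1 - 1/3
        assert diversity([a, b, c]) == pytest.approx(2.0 / 3.0)

    def test_single_molecule_undefined(self):
        with pytest.raises(UndefinedMetricError):
            diversity([mol_from_smiles("CC")])


class TestNormalizedScore:
    @pytest.mark.parametrize("score,n,expected", [
        (-12.0, 16, -3.0), (0.0, 7, 0.0), (-7.5, 25, -1.5),
    ])
    def test_arithmetic(self, score, n, expected):
        assert normalized_score(score, n) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            normalized_score(-5.0, 0)


class TestStructuralFilters:
    def test_clean_molecule_passes_all_catalogs(self):
        ok, hits = structural_filters(Chem.MolFromSmiles("CCO"),
                                      {"NIH", "PAINS", "Brenk"})
        assert ok and hits == []

    def test_quinone_fails_with_named_hit(self):
        ok, hits = structural_filters(Chem.MolFromSmiles("O=C1C=CC(=O)C=C1"),
                                      {"PAINS", "NIH"})
        assert not ok
        assert any("quinone" in h.lower() for h in hits)

    def test_empty_catalog_set_passes(self):
        ok, hits = structural_filters(Chem.MolFromSmiles("O=C1C=CC(=O)C=C1"),
                                      set())
        assert ok and hits == []

    def test_unknown_catalog_rejected(self):
        with pytest.raises(ConfigError):
            structural_filters(Chem.MolFromSmiles("CCO"), {"REOS"})


SUCCESS_POOL = [
    "CCO", "CC(=O)Nc1ccc(O)cc1", "c1ccc2[nH]ccc2c1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                       # expected passers
    "O=C1C=CC(=O)C=C1", "C=CC(=O)OC", "ClCCl", "ICI",
    "OC(=O)C(=O)O", "C=CC=O",                           # NIH-flagged
]


class TestSuccessRate:
    def test_all_pass(self):
        mols = [Chem.MolFromSmiles(s) for s in ["CCO", "c1ccc2[nH]ccc2c1"]]
        rates, empty = success_rate({"p": mols}, qed_min=0.19, sa_min=0.33)
        assert rates["p"] == 1.0 and empty == 0

    def test_all_fail_counts_empty_pocket(self):
        mols = [Chem.MolFromSmiles(s) for s in ["ClCCl", "ICI"]]
        rates, empty = success_rate({"p": mols}, qed_min=0.19, sa_min=0.33)
        assert rates["p"] == 0.0 and empty == 1

    def test_matches_per_molecule_recheck(self):
        mols = [Chem.MolFromSmiles(s) for s in SUCCESS_POOL]
        rates, empty = success_rate({"p": mols}, qed_min=0.19, sa_min=0.33)
        # oracle: independent per-molecule re-evaluation
        n_pass = sum(
            1 for m in mols
            if structural_filters(m, {"NIH"})[0]
            and qed(m) >= 0.19 and sa_score_normalized(m) >= 0.33
        )
        assert rates["p"] == n_pass / len(mols)
        assert n_pass == 4
        assert empty == 0

    def test_validity_flags_are_respected(self):
        mols = [Chem.MolFromSmiles("CCO")] * 3
        rates, empty = success_rate({"p": mols}, 0.19, 0.33,
                                    validity_flags={"p": [True, False, False]})
        assert rates["p"] == pytest.approx(1 / 3)


class TestTopK:
    def _poses(self, ref, shifts):
        return [Molecule3D(ref.atom_types, ref.positions + [s, 0, 0], ref.bonds)
                for s in shifts]

    def test_k1_is_argmax(self):
        ref = mol_from_smiles("c1ccncc1")
        mols = self._poses(ref, [3.0, 0.5, 1.5])
        top = topk_by_sc(mols, ref, 1)
        assert top[0] is mols[1]

    def test_ties_keep_input_order(self):
        ref = mol_from_smiles("c1ccncc1")
        mols = self._poses(ref, [1.0, 1.0, 1.0])
        top = topk_by_sc(mols, ref, 2)
        assert top[0] is mols[0] and top[1] is mols[1]

    def test_matches_full_sort_oracle(self):
        ref = mol_from_smiles("c1ccncc1")
        mols = self._poses(ref, [2.5, 0.2, 1.1, 3.8, 0.7])
        scores = [shape_color_similarity(m, ref) for m in mols]
        oracle = [mols[i] for i in np.argsort(-np.array(scores), kind="stable")[:3]]
        assert topk_by_sc(mols, ref, 3) == oracle

    def test_k_larger_than_set_warns_and_returns_all(self):
        ref = mol_from_smiles("c1ccncc1")
        mols = self._poses(ref, [1.0, 2.0])
        with pytest.warns(UserWarning):
            top = topk_by_sc(mols, ref, 5)
        assert len(top) == 2


class TestMetricConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            MetricConfig(fp_bits=1000)
        with pytest.raises(ConfigError):
            MetricConfig(sc_weights=(0.7, 0.7))
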