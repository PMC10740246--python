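import itertools
from collections import Counter

import numpy as np
import pytest
from rdkit import Chem

from confrank.baselines import (
    EnergyRanker,
    GeneratorOrderRanker,
    OracleRanker,
    RandomRanker,
    RGyrRanker,
    SasaRanker,
    TFD2SimRefMCSRanker,
    dihedral_deg,
    find_nearest_reference,
    match_conformers_by_mcs_torsions,
    mcs,
    tfd_mcs,
    thermal_energy_window,
    write_ranking_table,
)
from confrank.conformers import ConformerRecord, LabelledEnsemble, build_labelled_ensemble, generate_conformers
from confrank.structures import molecule_from_smiles


def _ensemble(rec, confs, labels=False):
    ens = LabelledEnsemble(mol_id=rec.mol_id, mol=rec.mol, conformers=list(confs), bioactive=[])
    return ens


@pytest.fixture(scope="module")
def butane_ensemble():
    rec = molecule_from_smiles("CCCC", "butane")
    confs = generate_conformers(rec, max_n=10, seed=2, prune_rms_thresh=-1.0)
    return rec, confs


@pytest.fixture(scope="module")
def chain_ensemble():
    """A flexible chain with clearly extended vs folded conformers."""
    rec = molecule_from_smiles("CCCCCCCCCC", "decane")
    confs = generate_conformers(rec, max_n=20, seed=4, prune_rms_thresh=-1.0)
    return _ensemble(rec, confs)


class TestPermutationContracts:
    def test_all_rankers_output_permutations(self, labelled_ensemble):
        rankers = [RandomRanker(seed=3), GeneratorOrderRanker(), EnergyRanker(), SasaRanker(), RGyrRanker(), OracleRanker()]
        expected = sorted(c.conf_id for c in labelled_ensemble.conformers)
        for ranker in rankers:
            res = ranker.rank(labelled_ensemble)
            assert sorted(res.order) == expected, ranker.name

    def test_reranking_is_idempotent(self, labelled_ensemble):
        for ranker in [GeneratorOrderRanker(), SasaRanker(), RGyrRanker(), OracleRanker()]:
            first = ranker.rank(labelled_ensemble)
            second = ranker.rank(labelled_ensemble)
            assert first.order == second.order, ranker.name


class TestRandomRanker:
    def test_seeded_reproducibility(self, labelled_ensemble):
        a = RandomRanker(seed=5).rank(labelled_ensemble)
        b = RandomRanker(seed=5).rank(labelled_ensemble)
        assert a.order == b.order

    def test_single_conformer(self, ibuprofen, ibuprofen_confs):
        ens = LabelledEnsemble(
            mol_id="x", mol=ibuprofen.mol, conformers=[ibuprofen_confs[0]], bioactive=[]
        )
        assert RandomRanker(seed=0).rank(ens).order == [ibuprofen_confs[0].conf_id]

    def test_permutations_uniform_over_seeds(self, ibuprofen):
        """Each of the 24 orderings of 4 conformers appears ~1/24 of the time."""
        rng = np.random.default_rng(0)
        confs = [
            ConformerRecord("m", k, rng.normal(size=(3, 3)), gen_order=k) for k in range(4)
        ]
        mol = Chem.MolFromSmiles("CCO")
        ens = LabelledEnsemble(mol_id="m", mol=mol, conformers=confs, bioactive=[])
        n_draws = 10_000
        ranker = RandomRanker(seed=123)
        counts = Counter(tuple(ranker.rank(ens).order) for _ in range(n_draws))
        assert len(counts) == 24
        expected = n_draws / 24
        sigma = np.sqrt(n_draws * (1 / 24) * (23 / 24))
        for count in counts.values():
            assert abs(count - expected) <= 4 * sigma


class TestGeneratorOrderRanker:
    def test_sorts_by_gen_order(self):
        rng = np.random.default_rng(1)
        confs = [
            ConformerRecord("m", cid, rng.normal(size=(3, 3)), gen_order=g)
            for cid, g in [(10, 2), (11, 0), (12, 1)]
        ]
        ens = LabelledEnsemble(mol_id="m", mol=Chem.MolFromSmiles("CCO"), conformers=confs, bioactive=[])
        assert GeneratorOrderRanker().rank(ens).order == [11, 12, 10]

    def test_missing_gen_order_rejected(self):
        confs = [ConformerRecord("m", 0, np.zeros((3, 3)))]
        ens = LabelledEnsemble(mol_id="m", mol=Chem.MolFromSmiles("CCO"), conformers=confs, bioactive=[])
        with pytest.raises(ValueError):
            GeneratorOrderRanker().rank(ens)


class TestEnergyRanker:
    def test_anti_butane_below_eclipsed(self, butane_ensemble):
        rec, confs = butane_ensemble
        ranker = EnergyRanker()
        # construct anti (180) and syn/eclipsed (0) rotamers from a generated one
        from rdkit.Chem import rdMolTransforms

        def rotamer(angle, cid):
            mol = Chem.Mol(rec.mol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(confs[0].coords):
                conf.SetAtomPosition(i, [float(v) for v in xyz])
            mol.RemoveAllConformers()
            k = mol.AddConformer(conf, assignId=True)
            rdMolTransforms.SetDihedralDeg(mol.GetConformer(k), 0, 1, 2, 3, angle)
            return ConformerRecord("butane", cid, np.array(mol.GetConformer(k).GetPositions()), gen_order=cid)

        anti, eclipsed = rotamer(180.0, 0), rotamer(0.0, 1)
        ens = LabelledEnsemble(mol_id="butane", mol=rec.mol, conformers=[eclipsed, anti], bioactive=[])
        res = EnergyRanker().rank(ens)
        assert res.order[0] == anti.conf_id

    def test_rigid_motion_leaves_energy_unchanged(self, butane_ensemble):
        rec, confs = butane_ensemble
        ranker = EnergyRanker()
        base = ranker._energy(rec.mol, confs[0])
        moved = ConformerRecord("butane", 9, confs[0].coords + np.array([10.0, -4.0, 2.0]))
        assert ranker._energy(rec.mol, moved) == pytest.approx(base, abs=1e-6)

    def test_duplicate_conformers_tie_broken_by_gen_order(self, butane_ensemble):
        rec, confs = butane_ensemble
        dup = [
            ConformerRecord("butane", 0, confs[0].coords.copy(), gen_order=1),
            ConformerRecord("butane", 1, confs[0].coords.copy(), gen_order=0),
        ]
        ens = LabelledEnsemble(mol_id="butane", mol=rec.mol, conformers=dup, bioactive=[])
        assert EnergyRanker().rank(ens).order == [1, 0]


class TestSurfaceRankers:
    def test_extended_chain_ranked_before_folded_hairpin(self, chain_ensemble):
        from rdkit.Chem import rdMolTransforms

        def rotamer(angles, cid):
            mol = Chem.Mol(chain_ensemble.mol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(chain_ensemble.conformers[0].coords):
                conf.SetAtomPosition(i, [float(v) for v in xyz])
            mol.RemoveAllConformers()
            k = mol.AddConformer(conf, assignId=True)
            for t, angle in enumerate(angles):
                rdMolTransforms.SetDihedralDeg(mol.GetConformer(k), t, t + 1, t + 2, t + 3, angle)
            return ConformerRecord("decane", cid, np.array(mol.GetConformer(k).GetPositions()), gen_order=cid)

        extended = rotamer([180.0] * 7, 0)  # all-anti chain
        folded = rotamer([180, 180, 60, 60, 60, 180, 180], 1)  # hairpin turn
        ens = LabelledEnsemble(
            mol_id="decane", mol=chain_ensemble.mol, conformers=[folded, extended], bioactive=[]
        )
        for ranker in (SasaRanker(), RGyrRanker()):
            assert ranker.rank(ens).order[0] == extended.conf_id, ranker.name

    def test_sasa_positive_and_rigid_invariant(self, chain_ensemble):
        ranker = SasaRanker()
        scores = ranker.score(chain_ensemble)
        assert np.all(scores > 0)
        moved = LabelledEnsemble(
            mol_id="decane",
            mol=chain_ensemble.mol,
            conformers=[
                ConformerRecord("decane", c.conf_id, c.coords + 7.0, gen_order=c.gen_order)
                for c in chain_ensemble.conformers
            ],
            bioactive=[],
        )
        np.testing.assert_allclose(ranker.score(moved), scores, atol=1e-6)

    def test_rgyr_closed_form_two_point_mass(self):
        mol = Chem.MolFromSmiles("[C][C]")  # two equal masses
        confs = [ConformerRecord("m", 0, np.array([[0.0, 0, 0], [2.0, 0, 0]]), gen_order=0)]
        ens = LabelledEnsemble(mol_id="m", mol=mol, conformers=confs, bioactive=[])
        assert RGyrRanker().score(ens)[0] == pytest.approx(1.0)

    def test_rgyr_single_atom_is_zero(self):
        mol = Chem.MolFromSmiles("[C]")
        ens = LabelledEnsemble(
            mol_id="m", mol=mol, conformers=[ConformerRecord("m", 0, np.zeros((1, 3)), gen_order=0)], bioactive=[]
        )
        assert RGyrRanker().score(ens)[0] == 0.0


class TestNearestReference:
    def test_self_similarity_is_one(self, ibuprofen):
        refs = [("ibuprofen", ibuprofen.mol), ("hexane", Chem.MolFromSmiles("CCCCCC"))]
        assert find_nearest_reference(ibuprofen.mol, refs) == "ibuprofen"

    def test_toluene_prefers_benzene_over_hexane(self):
        toluene = Chem.MolFromSmiles("Cc1ccccc1")
        refs = [("benzene", Chem.MolFromSmiles("c1ccccc1")), ("hexane", Chem.MolFromSmiles("CCCCCC"))]
        assert find_nearest_reference(toluene, refs) == "benzene"

    def test_zero_overlap_ties_break_lexicographically(self):
        probe = Chem.MolFromSmiles("[SiH4]")
        refs = [("b_ref", Chem.MolFromSmiles("CC")), ("a_ref", Chem.MolFromSmiles("CCC"))]
        assert find_nearest_reference(probe, refs) == "a_ref"

    def test_empty_reference_set_rejected(self, ibuprofen):
        with pytest.raises(ValueError):
            find_nearest_reference(ibuprofen.mol, [])


class TestMcs:
    def test_identical_molecules_full_mcs(self, ibuprofen):
        match = mcs(ibuprofen.mol, ibuprofen.mol, "self")
        assert match.n_heavy == ibuprofen.n_heavy_atoms
        assert len(match.pairs) == match.n_heavy

    def test_disjoint_element_sets_empty(self):
        assert mcs(Chem.MolFromSmiles("CCCC"), Chem.MolFromSmiles("[Si]([SiH3])([SiH3])[SiH3]"), "x").n_heavy == 0

    def test_enantiomer_center_excluded(self):
        r = Chem.MolFromSmiles("C[C@H](N)C(=O)O")
        s = Chem.MolFromSmiles("C[C@@H](N)C(=O)O")
        match = mcs(r, s, "mirror")
        assert match.n_heavy < r.GetNumAtoms()

    def test_mapping_is_injective(self, ibuprofen):
        other = molecule_from_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)OC", "ester")
        match = mcs(ibuprofen.mol, other.mol, "ester")
        lefts = [a for a, _ in match.pairs]
        rights = [b for _, b in match.pairs]
        assert len(set(lefts)) == len(lefts)
        assert len(set(rights)) == len(rights)


class TestTfdMcs:
    @pytest.fixture(scope="class")
    def pair(self):
        rec = molecule_from_smiles("CCCCc1ccc(CC(=O)NC)cc1", "flex")
        confs = generate_conformers(rec, max_n=8, seed=6, prune_rms_thresh=-1.0)
        match = mcs(rec.mol, rec.mol, "self")
        return rec, confs, match

    def test_identical_conformation_zero(self, pair):
        rec, confs, match = pair
        assert tfd_mcs(confs[0], confs[0], match, rec.mol) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_conformer_arguments(self, pair):
        rec, confs, match = pair
        ab = tfd_mcs(confs[0], confs[1], match, rec.mol)
        ba = tfd_mcs(confs[1], confs[0], match, rec.mol)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_bounded_unit_interval(self, pair):
        rec, confs, match = pair
        for a, b in itertools.combinations(confs, 2):
            assert 0.0 <= tfd_mcs(a, b, match, rec.mol) <= 1.0

    def test_single_torsion_max_deviation(self):
        """A 180-degree flip of the only torsion gives the maximal TFD."""
        rec = molecule_from_smiles("FCCF", "dfe")  # one torsion F-C-C-F
        confs = generate_conformers(rec, max_n=1, seed=1)
        from rdkit.Chem import rdMolTransforms

        mol = Chem.Mol(rec.mol)
        conf = Chem.Conformer(4)
        for i, xyz in enumerate(confs[0].coords):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        k = mol.AddConformer(conf, assignId=True)
        rdMolTransforms.SetDihedralDeg(mol.GetConformer(k), 0, 1, 2, 3, 0.0)
        a = ConformerRecord("dfe", 0, np.array(mol.GetConformer(k).GetPositions()))
        rdMolTransforms.SetDihedralDeg(mol.GetConformer(k), 0, 1, 2, 3, 180.0)
        b = ConformerRecord("dfe", 1, np.array(mol.GetConformer(k).GetPositions()))
        match = mcs(rec.mol, rec.mol, "self")
        assert tfd_mcs(a, b, match, rec.mol) == pytest.approx(1.0, abs=1e-6)


class TestTfdRanker:
    def test_identical_reference_molecule_rank1_score0(self, ibuprofen, ibuprofen_confs):
        bio = ConformerRecord("ibuprofen", 0, ibuprofen_confs[2].coords.copy(), source="bioactive")
        reference = build_labelled_ensemble(ibuprofen, ibuprofen_confs, [bio])
        ranker = TFD2SimRefMCSRanker().fit([reference])
        res = ranker.rank(reference)
        assert res.order[0] == ibuprofen_confs[2].conf_id
        assert res.scores[0] == pytest.approx(0.0, abs=1e-6)
        assert res.flags["reference_mol_id"] == "ibuprofen"

    def test_no_torsion_falls_back_to_generator_order(self):
        rec = molecule_from_smiles("CC", "ethane")  # two heavy atoms: no torsion
        confs = generate_conformers(rec, max_n=3, seed=1)
        bio = ConformerRecord("ethane", 0, confs[0].coords.copy(), source="bioactive")
        ens = build_labelled_ensemble(rec, confs, [bio])
        ranker = TFD2SimRefMCSRanker().fit([ens])
        res = ranker.rank(ens)
        assert res.flags.get("fallback") == "generator_order"
        assert sorted(res.order) == sorted(c.conf_id for c in confs)


class TestMatchByTorsions:
    def test_identical_ensembles_self_pairing(self, ibuprofen, ibuprofen_confs):
        ens = LabelledEnsemble(
            mol_id="ibuprofen", mol=ibuprofen.mol, conformers=ibuprofen_confs[:4], bioactive=[]
        )
        match = mcs(ibuprofen.mol, ibuprofen.mol, "self")
        pairs = match_conformers_by_mcs_torsions(ens, ens, match, bin_width_deg=10)
        for c in ens.conformers:
            assert (c.conf_id, c.conf_id) in pairs

    def test_pair_count_monotone_in_bin_width(self, ibuprofen, ibuprofen_confs):
        ens = LabelledEnsemble(
            mol_id="ibuprofen", mol=ibuprofen.mol, conformers=ibuprofen_confs[:6], bioactive=[]
        )
        match = mcs(ibuprofen.mol, ibuprofen.mol, "self")
        narrow = match_conformers_by_mcs_torsions(ens, ens, match, bin_width_deg=10)
        wide = match_conformers_by_mcs_torsions(ens, ens, match, bin_width_deg=20)
        assert len(wide) >= len(narrow)

    def test_bin_membership_rule(self):
        # 4 vs 6 degrees share the [0,10) bin; 4 vs 14 do not
        assert int(np.floor((4 + 180) / 10)) == int(np.floor((6 + 180) / 10))
        assert int(np.floor((4 + 180) / 10)) != int(np.floor((14 + 180) / 10))


class TestThermalWindow:
    def test_printed_value_3kbt_at_298K(self):
        assert thermal_energy_window(3, 298) == pytest.approx(1.78, abs=0.005)

    def test_zero_multiple(self):
        assert thermal_energy_window(0, 298) == 0.0

    def test_single_kbt(self):
        assert thermal_energy_window(1, 298) == pytest.approx(0.592, abs=0.0005)


def test_dihedral_sign_convention():
    coords = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    # compare against rdkit's dihedral on the same four points
    from rdkit.Chem import rdMolTransforms

    mol = Chem.MolFromSmiles("CCCC")
    conf = Chem.Conformer(4)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(conf)
    expected = rdMolTransforms.GetDihedralDeg(mol.GetConformer(0), 0, 1, 2, 3)
    assert dihedral_deg(coords, [0, 1, 2, 3]) == pytest.approx(expected, abs=1e-6)


def test_ranking_table_output(tmp_path, labelled_ensemble):
    res = OracleRanker().rank(labelled_ensemble)
    path = tmp_path / "rankings.tsv"
    write_ranking_table([res], path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 1 + labelled_ensemble.n_conformers
    assert lines[0].split("\t") == ["mol_id", "ranker", "rank", "conf_id", "score"]
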