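"""Fragment catalogs, MFF counts, atom attributions, MFF-MOE, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Crippen

from tpascreen.dataset_io import ModellingSample, encode_solvent
from tpascreen.featurization import (
    assemble_matrix,
    atom_attributions,
    build_catalog,
    descriptor_manifest,
    fragment_environments,
    general_descriptors,
    mff_featurize,
    mff_moe_features,
    FragmentCatalog,
)


class TestCatalog:
    def test_methane_radius0_single_key(self, mol):
        cat = build_catalog([mol("C")], radius=0, min_support=1)
        assert len(cat) == 1

    def test_benzene_radius1_two_equivalent_environments(self, mol):
        cat = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        # all atoms equivalent: one radius-0 key, one radius-1 key
        assert len(cat) == 2

    def test_min_support_prunes_singletons(self, mol):
        mols = [mol("c1ccccc1"), mol("c1ccccc1"), mol("CCO")]
        cat = build_catalog(mols, radius=1, min_support=2)
        # only benzene keys appear in >= 2 molecules
        bz = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        assert set(cat.entries) == set(bz.entries)

    def test_deterministic_and_lexicographic(self, mol):
        mols = [mol(s) for s in ("c1ccccc1", "CCO", "C=CC=C", "CC(=O)C")]
        c1 = build_catalog(mols, radius=2, min_support=1)
        c2 = build_catalog(list(reversed(mols)), radius=2, min_support=1)
        assert c1.entries == c2.entries
        assert list(c1.entries) == sorted(c1.entries)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_catalog([], radius=1)

    def test_json_roundtrip(self, mol, tmp_path):
        cat = build_catalog([mol("c1ccccc1"), mol("CCO")], radius=2, min_support=1)
        p = tmp_path / "cat.json"
        cat.to_json(p)
        back = FragmentCatalog.from_json(p)
        assert back.entries == cat.entries
        assert (back.radius, back.min_support) == (cat.radius, cat.min_support)


class TestMFFVector:
    def test_benzene_counts_six_and_six(self, mol):
        m = mol("c1ccccc1")
        cat = build_catalog([m], radius=1, min_support=1)
        vec = mff_featurize(m, cat).to_dense()
        assert sorted(vec.tolist()) == [6, 6]

    def test_disjoint_vocabulary_gives_zero_vector(self, mol):
        cat = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        vec = mff_featurize(mol("CCCC"), cat).to_dense()
        assert not vec.any()

    def test_biphenyl_doubles_benzene_radius0_count(self, mol):
        bz = mol("c1ccccc1")
        cat = build_catalog([bz], radius=0, min_support=1)
        v_bz = mff_featurize(bz, cat).to_dense()
        v_bp = mff_featurize(mol("c1ccc(-c2ccccc2)cc1"), cat).to_dense()
        assert v_bz.sum() == 6 and v_bp.sum() == 12

    def test_invariant_to_atom_reordering(self, mol, rng):
        mols = [mol(s) for s in (
            "c1ccc(/C=C/c2ccccc2)cc1", "CN(C)c1ccc(C=O)cc1", "Nc1ccc(cc1)[N+](=O)[O-]"
        )]
        cat = build_catalog(mols, radius=3, min_support=1)
        for m in mols:
            ref = mff_featurize(m, cat).to_dense()
            for _ in range(5):
                perm = rng.permutation(m.GetNumAtoms()).tolist()
                renum = Chem.RenumberAtoms(m, [int(i) for i in perm])
                assert (mff_featurize(renum, cat).to_dense() == ref).all()


class TestAtomAttributions:
    @pytest.mark.parametrize("smiles", ["C", "c1ccccc1", "CCO", "Nc1ccc(cc1)[N+](=O)[O-]"])
    def test_peoe_charge_conservation(self, mol, smiles):
        m = mol(smiles)
        total = atom_attributions(m, "PEOE-Charge").sum()
        formal = sum(a.GetFormalCharge() for a in m.GetAtoms())
        assert total == pytest.approx(formal, abs=1e-6)

    def test_logp_sums_to_whole_molecule_value(self, mol):
        for smi in ("c1ccccc1O", "CCO", "CN(C)c1ccc(C=O)cc1"):
            m = mol(smi)
            assert atom_attributions(m, "LogP").sum() == pytest.approx(
                Crippen.MolLogP(m), abs=1e-6
            )

    def test_mr_sums_to_whole_molecule_value(self, mol):
        m = mol("c1ccccc1O")
        assert atom_attributions(m, "MR").sum() == pytest.approx(
            Crippen.MolMR(m), abs=1e-6
        )

    def test_unsupported_property_rejected(self, mol):
        with pytest.raises(ValueError, match="unsupported"):
            atom_attributions(mol("C"), "dipole")


class TestMFFMOE:
    def test_singleton_molecule_all_aggregates_equal(self, mol):
        m = mol("C")
        cat = build_catalog([m], radius=0, min_support=1)
        attr = atom_attributions(m, "LogP")
        feats = mff_moe_features(m, cat, attr, "LogP")
        vals = set(round(v, 12) for v in feats.values())
        assert len(vals) == 1

    def test_max_geq_mean_geq_min(self, mol):
        mols = [mol(s) for s in ("Nc1ccc(cc1)[N+](=O)[O-]", "CN(C)c1ccc(C=O)cc1")]
        cat = build_catalog(mols, radius=2, min_support=1)
        for m in mols:
            for prop in ("PEOE-Charge", "LogP", "MR"):
                attr = atom_attributions(m, prop)
                f = mff_moe_features(m, cat, attr, prop)
                assert f[f"{prop}-Max"] >= f[f"{prop}-Mean"] >= f[f"{prop}-Min"]

    def test_no_catalog_fragments_yields_zeros(self, mol):
        cat = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        m = mol("CCCC")
        attr = atom_attributions(m, "LogP")
        feats = mff_moe_features(m, cat, attr, "LogP")
        assert all(v == 0.0 for v in feats.values())

    def test_nitro_raises_peoe_charge_max(self, mol):
        bz, nb = mol("c1ccccc1"), mol("c1ccccc1[N+](=O)[O-]")
        cat = build_catalog([bz, nb], radius=1, min_support=1)
        f_bz = mff_moe_features(bz, cat, atom_attributions(bz, "PEOE-Charge"), "PEOE-Charge")
        f_nb = mff_moe_features(nb, cat, atom_attributions(nb, "PEOE-Charge"), "PEOE-Charge")
        assert f_nb["PEOE-Charge-Max"] > f_bz["PEOE-Charge-Max"]


class TestGeneralDescriptors:
    def test_manifest_is_pinned_at_107(self):
        assert len(descriptor_manifest()) == 107

    def test_methane_molecular_weight(self, mol):
        desc = general_descriptors(mol("C"))
        assert desc["MolWt"] == pytest.approx(16.043, abs=0.01)

    def test_partial_charge_order_statistics(self, conjugation_fixture_mols):
        for smiles, m in conjugation_fixture_mols:
            d = general_descriptors(m)
            if np.isnan(d["MaxPartialCharge"]):
                continue
            assert d["MaxPartialCharge"] >= d["MinPartialCharge"], smiles
            assert d["MaxAbsPartialCharge"] == pytest.approx(
                max(abs(d["MaxPartialCharge"]), abs(d["MinPartialCharge"]))
            ), smiles


def _samples(smiles_list):
    tol = encode_solvent("toluene")
    return [
        ModellingSample(f"m{i}", smi, 1.0, 800.0, tol)
        for i, smi in enumerate(smiles_list)
    ]


class TestAssembleMatrix:
    SMILES = [
        "c1ccccc1", "CCO", "C=CC=C", "Cc1ccccc1", "c1ccncc1",
        "CC(=O)C", "C=Cc1ccccc1", "Oc1ccccc1", "CCN", "C=CC=CC=C",
    ]

    def test_block_widths_are_additive(self, mol):
        samples = _samples(self.SMILES)
        cat = build_catalog([mol(s) for s in self.SMILES], radius=2, min_support=1)
        fm = assemble_matrix(samples, catalog=cat)
        assert len(fm.feature_names) == len(cat) + 107 + 21 + 3 + 1
        assert set(fm.blocks.values()) == {"mff", "general", "conjugation", "experimental"}

    def test_single_sample_matrix(self, mol):
        samples = _samples(["c1ccccc1"])
        cat = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        fm = assemble_matrix(samples, catalog=cat)
        assert fm.df.shape[0] == 1
        assert fm.df.loc["m0", "Conju-Max-Distance"] == 3.0

    def test_row_permutation_preserves_values(self, mol):
        cat = build_catalog([mol(s) for s in self.SMILES], radius=2, min_support=1)
        fm1 = assemble_matrix(_samples(self.SMILES), catalog=cat)
        rev = _samples(self.SMILES)
        # re-id so the same molecule keeps its id after reversal
        fm2 = assemble_matrix(list(reversed(rev)), catalog=cat)
        pd.testing.assert_frame_equal(
            fm1.df.sort_index(), fm2.df.sort_index(), check_like=True
        )

    def test_no_nan_or_inf_after_imputation(self, mol):
        samples = _samples(self.SMILES)
        cat = build_catalog([mol(s) for s in self.SMILES], radius=2, min_support=1)
        fm = assemble_matrix(samples, catalog=cat, include_mff_moe=True)
        assert np.isfinite(fm.values).all()

    def test_mff_triplet_export_roundtrips_counts(self, mol, tmp_path):
        samples = _samples(["c1ccccc1", "CCO", "C=CC=C"])
        mols = [mol(s.smiles) for s in samples]
        cat = build_catalog(mols, radius=1, min_support=1)
        fm = assemble_matrix(samples, catalog=cat, blocks=("mff",))
        p = tmp_path / "mff.tsv"
        fm.write_mff_triplets(p)
        back = pd.read_csv(p, sep="\t")
        for row in back.itertuples():
            assert fm.df.loc[row.sample_id, f"MFF:{row.fragment}"] == row.count
        assert back["count"].sum() == fm.df.to_numpy().sum()

    def test_duplicate_column_rejected(self, mol):
        samples = _samples(["c1ccccc1", "CCO"])
        cat = build_catalog([mol("c1ccccc1")], radius=1, min_support=1)
        fm = assemble_matrix(samples, catalog=cat)
        with pytest.raises(ValueError, match="duplicate"):
            fm.with_column("MolWt", np.zeros(2))
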