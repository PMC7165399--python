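"""Reaction libraries, complementary libraries and the mutation operator."""
import json

import numpy as np
import pytest

from evochem import (MoleculeRecord, OperatorFailure, ReactionLoadError,
                     build_complementary_library, canonicalize,
                     compute_descriptors, load_reaction_library,
                     matching_reactions, mutate, self_test)
from evochem.reactions import enumerate_mutation_products

ESTERIFICATION = {
    "name": "esterification",
    "smirks": "[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]",
    "num_reactants": 2,
    "slot_queries": ["[CX3](=O)[OX2H1]", "[OX2H1][CX4]"],
    "source_set": "custom",
}


def write_library(tmp_path, entries, name="lib.json"):
    p = tmp_path / name
    p.write_text(json.dumps(entries))
    return p


class TestLoading:
    def test_bundled_set_sizes(self):
        assert len(load_reaction_library(None, "AutoClickChemRxn")) == 36
        assert len(load_reaction_library(None, "RobustRxn")) == 58
        allrxn = load_reaction_library(None, "AllRxn")
        assert len(allrxn) == 94
        assert allrxn.n_bimolecular == 79

    def test_single_reaction_custom_library(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, [ESTERIFICATION]))
        assert len(lib) == 1 and lib.n_bimolecular == 1

    def test_slot_template_mismatch_is_a_load_error(self, tmp_path):
        bad = dict(ESTERIFICATION, slot_queries=["[CX3](=O)[OX2H1]"])
        with pytest.raises(ReactionLoadError, match="slot"):
            load_reaction_library(write_library(tmp_path, [bad]))

    def test_unparsable_smirks_is_a_load_error(self, tmp_path):
        bad = dict(ESTERIFICATION, smirks="not a reaction")
        with pytest.raises(ReactionLoadError, match="esterification"):
            load_reaction_library(write_library(tmp_path, [bad]))

    def test_malformed_json_is_a_load_error(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text("{nope")
        with pytest.raises(ReactionLoadError, match="JSON"):
            load_reaction_library(p)

    def test_every_bundled_reaction_passes_its_example_self_test(self, all_rxn):
        results = self_test(all_rxn)
        assert all(results.values()), [k for k, v in results.items() if not v]


class TestMatching:
    def test_carboxylic_acid_matches_acid_slot(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, [ESTERIFICATION]))
        matches = matching_reactions("CC(=O)O", lib)
        assert [(spec.name, slot) for spec, slot in matches] == [("esterification", 0)]

    def test_methane_matches_nothing_in_all_rxn(self, all_rxn):
        assert matching_reactions("C", all_rxn) == []

    def test_empty_library_matches_nothing(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, []))
        assert matching_reactions("CCO", lib) == []


class TestComplementaryLibrary:
    def test_grouping_by_slot(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, [ESTERIFICATION]))
        comp = build_complementary_library(
            ["CCO", "CC(=O)O", "c1ccccc1"], lib)
        assert comp.group("esterification", 0) == ["CC(=O)O"]
        assert comp.group("esterification", 1) == ["CCO"]
        # benzene matches no slot and is discarded
        assert all("c1ccccc1" not in g for g in comp.groups.values())

    def test_per_group_cap_keeps_lowest_mw(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, [ESTERIFICATION]))
        comp = build_complementary_library(
            ["CCCO", "CCO"], lib, per_group_cap=1)
        assert comp.group("esterification", 1) == ["CCO"]

    def test_mw_cap_discards_heavy_candidates(self, tmp_path):
        lib = load_reaction_library(write_library(tmp_path, [ESTERIFICATION]))
        heavy_alcohol = "OCCCCCCCCCCCCCCCCCCCC"  # MW > 250
        assert compute_descriptors(heavy_alcohol).mw > 250
        comp = build_complementary_library([heavy_alcohol], lib)
        assert len(comp) == 0

    def test_empty_candidates_yield_empty_library(self, all_rxn):
        assert len(build_complementary_library([], all_rxn)) == 0


class TestMutate:
    def test_transesterification_worked_example(self, all_rxn):
        # phenyl benzoate + methanol -> methyl benzoate (+ discarded phenol);
        # the child is lighter than the parent ester
        phenyl_benzoate = canonicalize("O=C(Oc1ccccc1)c1ccccc1")
        spec = all_rxn.get("transesterification")
        products = enumerate_mutation_products(phenyl_benzoate, spec, 0, "CO")
        # the phenol co-product is discarded; only the ester child remains
        assert products == [canonicalize("COC(=O)c1ccccc1")]
        assert (compute_descriptors(products[0]).mw
                < compute_descriptors(phenyl_benzoate).mw)

    def test_click_cycloaddition_gives_triazole(self, all_rxn):
        azide = canonicalize("CCN=[N+]=[N-]")
        spec = all_rxn.get("azide_alkyne_cycloaddition_14")
        products = enumerate_mutation_products(azide, spec, 0, "C#CCC")
        assert products
        from rdkit import Chem
        triazole = Chem.MolFromSmarts("c1cn(nn1)")
        assert any(Chem.MolFromSmiles(p).HasSubstructMatch(triazole)
                   for p in products)

    def test_methane_fails_structurally(self, all_rxn, comp_library, rng):
        parent = MoleculeRecord(id="p", smiles="C")
        result = mutate(parent, all_rxn, comp_library, rng)
        assert isinstance(result, OperatorFailure)
        assert "no matching reaction" in result.reason

    def test_child_record_provenance(self, all_rxn, comp_library, rng):
        parent = MoleculeRecord(id="p", smiles="CC(=O)O", generation=2)
        child = mutate(parent, all_rxn, comp_library, rng, child_id="c1")
        assert not isinstance(child, OperatorFailure)
        assert child.origin == "mutation"
        assert child.parent_ids == ("p",)
        assert child.generation == 3
        assert child.reaction_name is not None

    def test_deterministic_under_fixed_seed(self, all_rxn, comp_library):
        parent = MoleculeRecord(id="p", smiles="CC(=O)O")
        a = mutate(parent, all_rxn, comp_library, np.random.default_rng(5))
        b = mutate(parent, all_rxn, comp_library, np.random.default_rng(5))
        assert a.smiles == b.smiles and a.reaction_name == b.reaction_name

    def test_provenance_reproduces_the_child(self, all_rxn, comp_library):
        # applying the recorded reaction (+ partner) to the recorded parent
        # must enumerate the child among its products
        rng = np.random.default_rng(11)
        parents = ["CC(=O)O", "CCO", "CCN", "CCN=[N+]=[N-]", "C#CCC"]
        checked = 0
        for i, smi in enumerate(parents * 4):
            parent = MoleculeRecord(id=f"p{i}", smiles=canonicalize(smi))
            child = mutate(parent, all_rxn, comp_library, rng)
            if isinstance(child, OperatorFailure):
                continue
            name, _, partner = child.reaction_name.partition("|")
            spec = all_rxn.get(name)
            found = []
            for slot in range(spec.num_reactants):
                try:
                    found += enumerate_mutation_products(
                        parent.smiles, spec, slot, partner or None)
                except Exception:
                    pass
            assert child.smiles in found
            checked += 1
        assert checked >= 10

    def test_all_products_canonicalize_and_both_mw_signs_occur(
            self, all_rxn, comp_library, seed_smiles):
        # MW drift: mutation can both grow and shrink molecules
        rng = np.random.default_rng(3)
        deltas = []
        n_children = 0
        for i in range(400):
            smi = seed_smiles[i % len(seed_smiles)]
            parent = MoleculeRecord(id=f"p{i}", smiles=smi)
            child = mutate(parent, all_rxn, comp_library, rng)
            if isinstance(child, OperatorFailure):
                continue
            n_children += 1
            assert canonicalize(child.smiles) == child.smiles
            deltas.append(compute_descriptors(child.smiles).mw
                          - compute_descriptors(smi).mw)
        assert n_children >= 200
        assert any(d > 0 for d in deltas) and any(d < 0 for d in deltas)
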