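import pytest

from cliffscout.chem import canonical
from cliffscout.mmp import (
    DEFAULT_RETRO_RULES,
    PairConfig,
    cuttable_bonds,
    find_matched_pairs,
    find_matched_pairs_brute_force,
    fragment,
    load_retro_rules,
    reassemble,
)
from cliffscout.synthetic import random_small_molecules


class TestFragment:
    def test_ethanol_every_acyclic_bond_once(self):
        frags = fragment("x", "CCO", k=1)
        assert len(frags) == 2
        got = {(f.core_smiles, f.substituents) for f in frags}
        assert got == {("OC[*:1]", ("*C",)), ("CC[*:1]", ("*O",))}

    def test_benzene_has_no_cuttable_bond(self):
        assert fragment("b", "c1ccccc1", k=1) == []

    def test_retrosynthetic_rules_cut_only_amide_bond(self):
        frags = fragment("n", "CC(=O)NC", k=1, rules="retrosynthetic")
        assert len(frags) == 1
        assert frags[0].substituents in (("*NC",), ("*C(C)=O",))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            fragment("x", "CCO", k=3)

    def test_substituent_size_cap(self):
        # cutting off a 14-heavy-atom chain is suppressed at the default cap
        smi = "C" * 14 + "O"
        subs = [f.substituents[0] for f in fragment("x", smi, k=1)]
        from cliffscout.chem import heavy_atoms

        assert all(heavy_atoms(s) <= 13 for s in subs)

    @pytest.mark.parametrize(
        "smiles", ["CCO", "Cc1ccc(OC)cc1", "CC(=O)Nc1ccccc1", "CCC(C)N"]
    )
    def test_reassembly_reproduces_parent(self, smiles):
        parent = canonical(smiles)
        for k in (1, 2):
            for fr in fragment("x", smiles, k=k):
                assert reassemble(fr.core_smiles, fr.substituents) == parent

    def test_retro_cuts_subset_of_all_bonds(self):
        from cliffscout.chem import mol_from_smiles

        for smi in ["CC(=O)Nc1ccccc1OC", "O=S(=O)(NCc1ccccc1)c1cccs1"]:
            mol = mol_from_smiles(smi)
            retro = set(cuttable_bonds(mol, "retrosynthetic"))
            allb = set(cuttable_bonds(mol, "all_single_bonds"))
            assert retro and retro <= allb

    def test_hydrogen_substituent_optional(self):
        plain = fragment("x", "Cc1ccccc1", k=1)
        with_h = fragment(
            "x", "Cc1ccccc1", k=1, include_hydrogen_substituents=True
        )
        assert not any(s == ("[H][*]",) for f in plain for s in [f.substituents])
        assert any(f.substituents == ("[H][*]",) for f in with_h)


class TestMatchedPairs:
    def test_single_site_exchange(self):
        pairs = find_matched_pairs({"a": "CCO", "b": "CCN"})
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.id_a, p.id_b, p.n_sites) == ("a", "b", 1)
        assert p.exchanged == (("*O", "*N"),)

    def test_identical_structures_never_pair(self):
        assert find_matched_pairs({"a": "CCO", "b": "OCC"}) == []

    def test_benzylic_core(self):
        pairs = find_matched_pairs({"a": "OCc1ccccc1", "b": "NCc1ccccc1"})
        assert len(pairs) == 1
        assert pairs[0].core_smiles == "c1ccc(C[*:1])cc1"

    def test_dual_site_needs_k2(self):
        st = {"a": "Cc1ccc(OC)cc1", "b": "CCc1ccc(OCC)cc1"}
        assert find_matched_pairs(st, PairConfig(k_max=1)) == []
        pairs = find_matched_pairs(st, PairConfig(k_max=2))
        assert [p.n_sites for p in pairs] == [2]

    def test_pair_is_unordered(self):
        a = find_matched_pairs({"a": "CCO", "b": "CCN"})
        b = find_matched_pairs({"b": "CCN", "a": "CCO"})
        assert a == b

    def test_h_to_methyl_detected_with_flag(self):
        st = {"tol": "Cc1ccccc1", "benz": "c1ccccc1"}
        assert find_matched_pairs(st) == []
        pairs = find_matched_pairs(st, PairConfig(include_hydrogen_substituents=True))
        assert len(pairs) == 1
        assert ("[H][*]", "*C") in pairs[0].exchanged or ("*C", "[H][*]") in pairs[0].exchanged

    def test_retro_pairs_nested_in_all_bond_pairs(self):
        st = {
            "a": "CC(=O)Nc1ccc(C)cc1",
            "b": "CC(=O)Nc1ccc(CC)cc1",
            "c": "CCC(=O)Nc1ccc(C)cc1",
        }
        retro = find_matched_pairs(st, PairConfig(rules="retrosynthetic"))
        allb = find_matched_pairs(st, PairConfig(rules="all_single_bonds"))
        assert {p.key for p in retro} <= {p.key for p in allb}

    def test_index_equals_brute_force_on_random_molecules(self):
        structures = random_small_molecules(40, max_heavy=12, seed=3)
        for cfg in (PairConfig(k_max=1), PairConfig(k_max=2)):
            indexed = find_matched_pairs(structures, cfg)
            brute = find_matched_pairs_brute_force(structures, cfg)
            assert indexed == brute

    def test_size_restrictions_enforced(self):
        # swapped 10-atom ring systems against a 9-atom core: rejected at
        # the default 2x core/substituent ratio, accepted when relaxed
        st = {
            "a": "O=C(NCc1ccccc1)c1ccc2ccccc2c1",
            "b": "O=C(NCc1ccccc1)c1ccc2ncccc2c1",
        }
        strict = find_matched_pairs(st, PairConfig(min_core_ratio=2.0))
        loose = find_matched_pairs(st, PairConfig(min_core_ratio=0.5))
        assert strict == []
        assert len(loose) == 1


class TestRetroRules:
    def test_default_rules_valid_and_loadable(self, tmp_path):
        import yaml

        path = tmp_path / "rules.yaml"
        path.write_text(yaml.safe_dump(DEFAULT_RETRO_RULES))
        assert load_retro_rules(path) == DEFAULT_RETRO_RULES

    def test_malformed_rule_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("- name: broken\n  pattern: CC\n")
        with pytest.raises(ValueError):
            load_retro_rules(path)

    def test_invalid_smarts_named_in_error(self):
        with pytest.raises(ValueError, match="badrule"):
            fragment(
                "x", "CCO", k=1, rules="retrosynthetic",
                retro_rules=[{"name": "badrule", "smarts": "[[["}],
            )
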