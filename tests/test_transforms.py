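"""Biotransformation rules, candidate enumeration, suspect-list loading."""

import random

import pytest

from phytoscreen.chem import parse_formula
from phytoscreen.transforms import (AMINO_ACID_FORMULAS, PARENT_DRUGS,
                                    TransformationRule, builtin_rules,
                                    enumerate_candidates, load_suspect_list)

#: Sum formulas of the 11 observed metabolite species (isomer pairs share one).
OBSERVED_METABOLITE_FORMULAS = {
    "C17H17Cl2NO",     # OH-STR (2 isomers)
    "C25H24Cl2N2O",    # DM-STR + Phe
    "C25H24Cl2N2O2",   # DM-STR + Tyr / OH-DM-STR + Phe
    "C18H21ClN2",      # DM-CLP
    "C19H23ClN2O",     # OH-CLP (2 isomers)
    "C18H21ClN2O",     # OH-DM-CLP
    "C19H22ClN5O2",    # OH-TZN
    "C10H13ClN2",      # mCPP
}


class TestBuiltinRules:
    def test_core_rules_present(self):
        names = {r.name for r in builtin_rules()}
        assert {"hydroxylation", "demethylation", "Phe-conjugation",
                "Tyr-conjugation", "mCPP-cleavage"} <= names

    def test_phe_conjugation_delta_is_condensation(self):
        rule = next(r for r in builtin_rules() if r.name == "Phe-conjugation")
        assert dict(rule.delta) == {"C": 9, "H": 9, "N": 1, "O": 1}

    def test_hydroxylation_of_sertraline(self):
        rule = next(r for r in builtin_rules() if r.name == "hydroxylation")
        out = rule.apply(parse_formula("C17H17Cl2N"))
        assert out.hill() == "C17H17Cl2NO"
        from phytoscreen.chem import protonated_mz
        assert round(protonated_mz(out), 4) == 322.0760

    def test_cleavage_only_applies_to_trazodone(self):
        rule = next(r for r in builtin_rules() if r.name == "mCPP-cleavage")
        assert rule.apply(parse_formula(PARENT_DRUGS["TZN"])).hill() == "C10H13ClN2"
        assert rule.apply(parse_formula(PARENT_DRUGS["STR"])) is None

    def test_full_amino_acid_set_available(self):
        assert len(AMINO_ACID_FORMULAS) == 20
        rules = builtin_rules(amino_acids=tuple(AMINO_ACID_FORMULAS))
        assert sum(r.name.endswith("-conjugation") for r in rules) == 20

    def test_rule_requires_exactly_one_of_delta_product(self):
        with pytest.raises(ValueError):
            TransformationRule("bad", delta={"O": 1},
                               product=parse_formula("CH4"))
        with pytest.raises(ValueError):
            TransformationRule("bad")


class TestEnumeration:
    def test_depth_zero_is_parent_only(self):
        cands = enumerate_candidates("CLP", builtin_rules(), max_depth=0)
        assert len(cands) == 1
        assert cands[0].is_parent
        assert cands[0].formula.hill() == "C19H23ClN2"

    def test_clp_depth_two_contains_observed_metabolites(self):
        cands = enumerate_candidates("CLP", builtin_rules(), max_depth=2)
        by_formula = {c.formula.hill(): c for c in cands}
        assert round(by_formula["C19H23ClN2O"].theoretical_mz, 4) == 331.1572
        assert round(by_formula["C18H21ClN2"].theoretical_mz, 4) == 301.1466
        assert round(by_formula["C18H21ClN2O"].theoretical_mz, 4) == 317.1415

    def test_str_depth_three_contains_conjugates(self):
        formulas = {c.formula.hill()
                    for c in enumerate_candidates("STR", builtin_rules(), max_depth=3)}
        assert "C25H24Cl2N2O" in formulas     # DM-STR + Phe
        assert "C25H24Cl2N2O2" in formulas    # OH-DM-STR + Phe / DM-STR + Tyr

    def test_depth_monotonicity(self):
        sets = [
            {c.formula.hill() for c in enumerate_candidates("STR", builtin_rules(),
                                                            max_depth=d)}
            for d in range(4)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_rule_order_does_not_matter(self):
        rules = list(builtin_rules())
        reference = enumerate_candidates("TZN", rules, max_depth=3)
        rng = random.Random(0)
        for _ in range(3):
            rng.shuffle(rules)
            shuffled = enumerate_candidates("TZN", rules, max_depth=3)
            assert [c.formula for c in shuffled] == [c.formula for c in reference]
            assert [c.chains for c in shuffled] == [c.chains for c in reference]

    def test_no_negative_counts_and_no_duplicate_chains(self):
        for parent in PARENT_DRUGS:
            cands = enumerate_candidates(parent, builtin_rules(), max_depth=3)
            formulas = [c.formula for c in cands]
            assert len(set(formulas)) == len(formulas)
            for c in cands:
                assert all(n >= 0 for _, n in c.formula)
                assert len(set(c.chains)) == len(c.chains)

    def test_collapsed_formula_retains_all_chains(self):
        cands = enumerate_candidates("CLP", builtin_rules(), max_depth=2)
        ohdm = next(c for c in cands if c.formula.hill() == "C18H21ClN2O")
        assert ("demethylation", "hydroxylation") in ohdm.chains
        assert ("hydroxylation", "demethylation") in ohdm.chains

    def test_full_observed_coverage_at_depth_three(self):
        formulas = set()
        for parent in PARENT_DRUGS:
            formulas |= {c.formula.hill()
                         for c in enumerate_candidates(parent, builtin_rules(),
                                                       max_depth=3)}
        assert OBSERVED_METABOLITE_FORMULAS <= formulas


class TestSuspectList:
    def test_shipped_reconstruction_loads_and_covers_observed(self):
        from phytoscreen.transforms import reconstructed_suspect_list

        cands = reconstructed_suspect_list()
        assert len(cands) == 21
        assert all(c.source == "suspect_list" for c in cands)
        formulas = {c.formula.hill() for c in cands}
        assert OBSERVED_METABOLITE_FORMULAS <= formulas


    def test_round_trip(self, tmp_path):
        p = tmp_path / "suspects.csv"
        p.write_text("name,formula,parent,expected_rt_min\n"
                     "mCPP,C10H13ClN2,TZN,3.0\n"
                     "OH-STR,C17H17Cl2NO,STR,\n")
        cands = load_suspect_list(p)
        assert len(cands) == 2
        assert cands[0].source == "suspect_list"
        assert round(cands[0].theoretical_mz, 4) == 197.0840
        assert cands[0].expected_rt == 3.0
        assert cands[1].expected_rt is None

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert load_suspect_list(p) == []

    def test_invalid_formula_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,formula\nok,H2O\nbad,Xx2\n")
        with pytest.raises(ValueError, match="row 2"):
            load_suspect_list(p)
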