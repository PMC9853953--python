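"""Formula parsing, monoisotopic masses, ion species, SDF normalization, matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfeptr.annotate import (
    ION_SPECIES,
    IonCandidate,
    enumerate_candidates,
    hill_formula,
    match_ions,
    monoisotopic_mass,
    normalize_structures,
    parse_formula,
    theoretical_mz,
)
from sfeptr.synthetic import make_structure_fixture


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C18H34O2", {"C": 18, "H": 34, "O": 2}),
            ("C6H18N3O6P3", {"C": 6, "H": 18, "N": 3, "O": 6, "P": 3}),
            ("Ca(OH)2", {"Ca": 1, "O": 2, "H": 2}),
            ("C15H21BrO", {"C": 15, "H": 21, "Br": 1, "O": 1}),
            ("", {}),
        ],
    )
    def test_examples(self, formula, expected):
        assert parse_formula(formula) == expected

    def test_roundtrip_through_hill(self):
        comp = {"C": 20, "H": 32, "O": 2}
        assert parse_formula(hill_formula(comp)) == comp

    @pytest.mark.parametrize("bad", ["C6(H3", "C6)2", "(", "2H"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C18H34O2", 282.256),  # oleic acid
            ("C20H32O2", 304.240),  # arachidonic acid
            ("C8H10N4O2", 194.080),  # caffeine
        ],
    )
    def test_reference_compounds(self, formula, expected):
        assert round(monoisotopic_mass(formula), 3) == expected

    def test_empty_composition_is_zero(self):
        assert monoisotopic_mass({}) == 0.0

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            monoisotopic_mass({"Xx": 1})

    def test_agrees_with_rdkit_exact_mass(self, fixture_sdf):
        """Independent oracle: rdkit's exact molecular weight on real structures."""
        from rdkit import Chem
        from rdkit.Chem import rdMolDescriptors

        supplier = Chem.SDMolSupplier()
        supplier.SetData(fixture_sdf, sanitize=True)
        checked = 0
        for mol in supplier:
            if mol is None or len(Chem.GetMolFrags(mol)) > 1:
                continue
            if any(a.GetIsotope() for a in mol.GetAtoms()):
                continue
            comp: dict[str, int] = {}
            for atom in mol.GetAtoms():
                comp[atom.GetSymbol()] = comp.get(atom.GetSymbol(), 0) + 1
                comp["H"] = comp.get("H", 0) + atom.GetTotalNumHs()
            assert monoisotopic_mass(comp) == pytest.approx(
                rdMolDescriptors.CalcExactMolWt(mol), abs=1e-4
            )
            checked += 1
        assert checked > 5


class TestIonSpecies:
    def test_positive_negative_deltas_cancel_exactly(self):
        assert ION_SPECIES["[M+H]+"].delta_mass + ION_SPECIES["[M-H]-"].delta_mass == 0.0
        assert ION_SPECIES["[M]+"].delta_mass + ION_SPECIES["[M]-"].delta_mass == 0.0
        assert ION_SPECIES["[M-OH]+"].delta_mass + ION_SPECIES["[M+OH]-"].delta_mass == 0.0

    @pytest.mark.parametrize(
        "formula,species,expected",
        [
            ("C6H18N3O6P3", "[M+H]+", 322.048),
            ("C16H12O6", "[M]+", 300.063),
            ("C20H32O2", "[M-H]-", 303.233),
        ],
    )
    def test_theoretical_mz_examples(self, formula, species, expected):
        assert round(theoretical_mz(formula, species), 3) == expected

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mz({"H": 1}, "[M-OH]+")

    def test_enumerate_candidates_polarity(self):
        res = normalize_structures(make_structure_fixture(6, seed=1))
        pos = enumerate_candidates(res.formulas, "positive")
        neg = enumerate_candidates(res.formulas, "negative")
        assert len(pos) == len(neg) == 3 * len(res.formulas)
        assert all(c.theoretical_mz > 0 for c in pos)
        mzs = [c.theoretical_mz for c in pos]
        assert mzs == sorted(mzs)
        with pytest.raises(ValueError):
            enumerate_candidates(res.formulas, "both")

    def test_ammonium_rule_optional(self):
        res = normalize_structures(make_structure_fixture(4, seed=1))
        with_nh4 = enumerate_candidates(res.formulas, "positive", include_ammonium=True)
        assert len(with_nh4) == 4 * len(res.formulas)


class TestNormalizeStructures:
    def test_salt_reduces_to_acid_formula(self):
        # records 1-4 of the fixture: acid, its Na salt, a d2 variant, a duplicate
        res = normalize_structures(make_structure_fixture(4, seed=0))
        assert [f.formula for f in res.formulas] == ["C18H34O2"]

    def test_isotope_substitution_and_dedup(self):
        res = normalize_structures(make_structure_fixture(4, seed=0))
        # all four records normalize to the same oleic acid structure
        assert res.n_unique_structures == 1
        assert res.formulas[0].n_structures == 1

    def test_distinct_isomers_counted(self):
        from io import StringIO

        from rdkit import Chem

        buf = StringIO()
        writer = Chem.SDWriter(buf)
        for smi in (
            r"CCCCC/C=C\C/C=C\C/C=C\C/C=C\CCCC(=O)O",
            r"CCCCCCC/C=C\C/C=C\C/C=C\C/C=C\CC(=O)O",
        ):
            writer.write(Chem.MolFromSmiles(smi))
        writer.close()
        res = normalize_structures(buf.getvalue())
        assert len(res.formulas) == 1
        assert res.formulas[0].formula == "C20H32O2"
        assert res.formulas[0].n_structures == 2

    def test_unparseable_record_skipped(self, fixture_sdf):
        broken = fixture_sdf + "\ngarbage\nnot a molfile\n$$$$\n"
        res = normalize_structures(broken)
        assert res.n_skipped >= 1
        assert res.n_parsed == res.n_input - res.n_skipped

    def test_mass_cutoff(self, fixture_sdf):
        res = normalize_structures(fixture_sdf, max_mass=300.0)
        assert all(f.monoisotopic_mass <= 300.0 for f in res.formulas)


def _brute_force_matches(observed, candidates, tol_mda):
    out = []
    for mz, _, _ in observed:
        for c in candidates:
            if abs(mz - c.theoretical_mz) <= tol_mda * 1e-3:
                out.append((round(mz, 6), c.formula, c.species))
    return sorted(out)


class TestMatchIons:
    def test_arachidonic_type_match(self):
        cand = [IonCandidate("C20H32O2", "[M-H]-", theoretical_mz("C20H32O2", "[M-H]-"), 41)]
        matches = match_ions([(303.233, 0.5, 3)], cand, tolerance_mda=3.0)
        assert len(matches) == 1
        assert abs(matches[0].delta_m_mda) <= 0.5
        assert matches[0].isomer_extra == 41

    def test_tight_tolerance_forces_miss(self):
        cand = [IonCandidate("C20H32O2", "[M-H]-", theoretical_mz("C20H32O2", "[M-H]-"), 0)]
        assert match_ions([(303.233, 0.5, 3)], cand, tolerance_mda=0.01) == []

    def test_replicate_sd_gate(self):
        cand = [IonCandidate("C20H32O2", "[M-H]-", theoretical_mz("C20H32O2", "[M-H]-"), 0)]
        # SD gate of 0.01 mDa rejects; SD gate of 3 mDa accepts
        assert match_ions([(303.233, 0.01, 3)], cand, gate="replicate_sd") == []
        assert len(match_ions([(303.233, 3.0, 3)], cand, gate="replicate_sd")) == 1

    def test_matches_sorted_by_abs_delta(self):
        cands = [
            IonCandidate("A", "[M+H]+", 300.0005, 0),
            IonCandidate("B", "[M+H]+", 299.9999, 0),
        ]
        matches = match_ions([(300.0, 0.0, 1)], cands, tolerance_mda=3.0)
        assert [m.formula for m in matches] == ["B", "A"]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        observed=st.lists(st.floats(100, 1000), max_size=40),
        theo=st.lists(st.floats(100, 1000), max_size=40),
        tol_mda=st.floats(0.01, 10),
    )
    def test_agrees_with_brute_force(self, observed, theo, tol_mda):
        obs = [(mz, 0.0, 1) for mz in sorted(observed)]
        cands = [IonCandidate(f"F{i}", "[M+H]+", mz, 0) for i, mz in enumerate(theo)]
        got = sorted(
            (round(m.observed_mz_mean, 6), m.formula, m.species)
            for m in match_ions(obs, cands, tol_mda)
        )
        assert got == _brute_force_matches(obs, cands, tol_mda)

    def test_brute_force_oracle_large_random_lists(self, rng):
        obs = [(mz, 0.0, 1) for mz in np.sort(rng.uniform(100, 1000, 500))]
        cands = [
            IonCandidate(f"F{i}", "[M+H]+", mz, 0)
            for i, mz in enumerate(rng.uniform(100, 1000, 500))
        ]
        got = sorted(
            (round(m.observed_mz_mean, 6), m.formula, m.species)
            for m in match_ions(obs, cands, 3.0)
        )
        assert got == _brute_force_matches(obs, cands, 3.0)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError):
            match_ions([], [], gate="bogus")
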