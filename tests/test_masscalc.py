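"""Mass calculus: peptide masses, modification offsets, delta matching."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pmass

from oligophos.masscalc import (
    ElementTable,
    InvalidHypothesisError,
    InvalidSequenceError,
    ModComposition,
    OPEN_SEARCH_OFFSETS,
    composition_delta,
    enumerate_hypotheses,
    intact_shift,
    match_delta,
    peptide_neutral_mass,
    precursor_mz,
)

#: printed open-search offsets the default hypothesis space must explain
ASSIGNABLE_OFFSETS = {
    79.9666: (1, 0, 0),  # (n_phos, n_fe, n_al)
    159.933: (2, 0, 0),
    212.845: (2, 1, 0),
    263.8566: (3, 0, 1),
    292.8104: (3, 1, 0),
    343.823: (4, 0, 1),
    372.7767: (4, 1, 0),
    452.7431: (5, 1, 0),
    585.6209: (6, 2, 0),
}


class TestPeptideNeutralMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("PEPTIDE", 799.35996), ("G", 75.03203), ("VMLGETNPADSKPGTIR", None)],
    )
    def test_known_masses(self, seq, expected):
        m = peptide_neutral_mass(seq)
        if expected is not None:
            assert m == pytest.approx(expected, abs=1e-4)
        # independent oracle: pyteomics' own residue/element tables
        assert m == pytest.approx(pmass.calculate_mass(sequence=seq), abs=1e-4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidSequenceError):
            peptide_neutral_mass("")

    def test_unknown_residue_named_with_position(self):
        with pytest.raises(InvalidSequenceError, match="'B' at position 3"):
            peptide_neutral_mass("AABAA")

    def test_mods_are_additive(self):
        comp = ModComposition(n_phos=3, n_fe=1)
        assert peptide_neutral_mass("AST", (comp,)) == pytest.approx(
            peptide_neutral_mass("AST") + comp.delta_mass, abs=1e-9
        )

    @pytest.mark.parametrize("aa", list("GASKRH"))
    def test_residue_mass_from_elemental_formula(self, aa):
        formula = ElementTable.residue_formulas[aa]
        assert ElementTable.residue_mass(aa) == pytest.approx(
            ElementTable.formula_mass(formula), abs=1e-12
        )
        assert ElementTable.residue_mass(aa) == pytest.approx(
            pmass.std_aa_mass[aa], abs=1e-4
        )


class TestCompositionDelta:
    @pytest.mark.parametrize(
        "kwargs,expected,tol",
        [
            (dict(n_phos=2), 159.933, 0.005),
            (dict(n_phos=3, n_fe=1), 292.8104, 0.005),
            (dict(n_phos=0), 0.0, 1e-12),
            (dict(n_phos=6, n_fe=2), 585.6209, 0.005),
        ],
    )
    def test_printed_offsets(self, kwargs, expected, tol):
        assert composition_delta(ModComposition(**kwargs)) == pytest.approx(
            expected, abs=tol
        )

    def test_metal_requires_chelating_chain(self):
        with pytest.raises(InvalidHypothesisError):
            ModComposition(n_phos=1, n_fe=1)
        with pytest.raises(InvalidHypothesisError):
            ModComposition(n_phos=3, n_fe=1, n_al=1)

    def test_delta_against_elemental_oracle(self, default_space):
        """Every default hypothesis recomputed from raw formulas (pyteomics)."""
        for comp in default_space:
            oracle = (
                comp.n_phos * pmass.calculate_mass(formula="HPO3")
                + comp.n_fe
                * (pmass.calculate_mass(formula="Fe") - 3 * pmass.calculate_mass(formula="H"))
                + comp.n_al
                * (pmass.calculate_mass(formula="Al") - 3 * pmass.calculate_mass(formula="H"))
                + comp.n_na
                * (pmass.calculate_mass(formula="Na") - pmass.calculate_mass(formula="H"))
                + comp.n_ox * pmass.calculate_mass(formula="O")
            )
            assert comp.delta_mass == pytest.approx(oracle, abs=1e-4)

    @given(
        a=st.tuples(st.integers(0, 3), st.integers(0, 1), st.integers(0, 1),
                    st.integers(0, 1), st.integers(0, 1)),
        b=st.tuples(st.integers(0, 3), st.integers(0, 1), st.integers(0, 1),
                    st.integers(0, 1), st.integers(0, 2)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_additivity(self, a, b):
        """delta(a + b) = delta(a) + delta(b) for valid component-wise sums."""
        try:
            ca, cb = ModComposition(*a), ModComposition(*b)
            csum = ModComposition(*(x + y for x, y in zip(a, b)))
        except InvalidHypothesisError:
            return
        assert csum.delta_mass == pytest.approx(
            ca.delta_mass + cb.delta_mass, abs=1e-9
        )


class TestEnumerateAndMatch:
    def test_trivial_bounds_give_empty_hypothesis(self):
        space = enumerate_hypotheses(max_phos=0, max_metal=0, max_ox=0)
        assert space == [ModComposition()]

    def test_small_space_brute_force(self):
        space = enumerate_hypotheses(max_phos=2, max_metal=1, max_ox=0)
        assert {(c.n_phos, c.n_fe, c.n_al) for c in space} == {
            (0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0), (2, 0, 1)
        }

    def test_sorted_and_deduplicated(self, default_space):
        deltas = [c.delta_mass for c in default_space]
        assert deltas == sorted(deltas)
        assert len(set(default_space)) == len(default_space)

    def test_printed_offsets_uniquely_covered(self, default_space):
        """Each printed offset matched by exactly one hypothesis at 0.005 Da."""
        for offset in ASSIGNABLE_OFFSETS:
            m = match_delta(offset, default_space, tolerance=0.005)
            assert len(m.hypotheses) == 1, offset
            comp = m.best
            assert (comp.n_phos, comp.n_fe, comp.n_al) == ASSIGNABLE_OFFSETS[offset]

    def test_acceptance_classes_never_collide(self, default_space):
        """No two hypotheses within 0.003 Da for the oligophospho classes."""
        keys = set(ASSIGNABLE_OFFSETS.values())
        used = [c for c in default_space if (c.n_phos, c.n_fe, c.n_al) in keys
                and c.n_na == 0 and c.n_ox == 0]
        for a, b in itertools.combinations(default_space, 2):
            if a in used or b in used:
                assert abs(a.delta_mass - b.delta_mass) > 0.003, (a, b)

    def test_match_is_inverse_of_enumeration(self, default_space):
        for comp in default_space:
            m = match_delta(comp.delta_mass, default_space, tolerance=0.005)
            assert m.best == comp

    def test_unassigned_offsets_report_no_match(self, default_space):
        for offset in (184.0552, 98.0492, 390.788, 94.0186):
            assert offset in OPEN_SEARCH_OFFSETS
            assert match_delta(offset, default_space, tolerance=0.005).best is None

    @pytest.mark.parametrize(
        "observed,expected",
        [(159.933, (2, 0)), (0.0001, (0, 0)), (212.845, (2, 1))],
    )
    def test_match_examples(self, observed, expected, default_space):
        best = match_delta(observed, default_space, tolerance=0.01).best
        assert (best.n_phos, best.n_fe) == expected

    def test_ties_broken_by_parsimony(self):
        """Equal |error| candidates rank by fewest components."""
        space = [ModComposition(), ModComposition(n_phos=1)]
        midpoint = ModComposition(n_phos=1).delta_mass / 2
        m = match_delta(midpoint, space, tolerance=45.0)
        assert len(m.hypotheses) == 2
        assert m.best == ModComposition()


class TestMzAndIntactShift:
    @pytest.mark.parametrize(
        "neutral,z,expected",
        [(1000.0, 1, 1001.00728), (1000.0, 2, 501.00728), (0.0, 1, 1.00728)],
    )
    def test_precursor_mz(self, neutral, z, expected):
        assert precursor_mz(neutral, z) == pytest.approx(expected, abs=1e-4)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            precursor_mz(1000.0, 0)

    @pytest.mark.parametrize(
        "before,after,rounded,expected",
        [
            (dict(n_phos=1), dict(n_phos=2), True, 80),
            (dict(), dict(n_phos=2), True, 160),
            (dict(n_phos=2), dict(n_phos=2), False, 0.0),
            (dict(), dict(n_phos=2, n_al=1), True, 184),
            (dict(), dict(n_phos=2, n_fe=1), True, 213),
        ],
    )
    def test_intact_shifts(self, before, after, rounded, expected):
        shift = intact_shift(
            ModComposition(**before), ModComposition(**after), rounding=rounded
        )
        assert shift == expected
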