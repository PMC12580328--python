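"""Monoisotopic mass calculus for oligophosphopeptides and trivalent-metal adducts.

Protein oligophosphorylation attaches a linear chain of up to six
phosphoanhydride-linked phosphate groups to a single Ser/Thr side chain.
Such chains are strong chelators and are typically observed in the mass
spectrometer as Fe(III) or Al(III) adducts, in which the metal cation
replaces three acidic protons of the chain.  This module provides:

* a pinned table of atomic and residue monoisotopic masses
  (:class:`ElementTable`),
* :class:`ModComposition` — one modification hypothesis (chain length,
  metal substitutions, Na substitutions, Met oxidations) and its neutral
  mass offset,
* enumeration of the hypothesis space an open search should consider and
  matching of observed delta masses against it.

All masses are monoisotopic and in daltons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "ElementTable",
    "ELEMENTS",
    "ModComposition",
    "MatchResult",
    "InvalidSequenceError",
    "InvalidHypothesisError",
    "peptide_neutral_mass",
    "composition_delta",
    "enumerate_hypotheses",
    "match_delta",
    "precursor_mz",
    "intact_shift",
    "OPEN_SEARCH_OFFSETS",
]


class InvalidSequenceError(ValueError):
    """A peptide/protein sequence contains a non-standard residue letter."""


class InvalidHypothesisError(ValueError):
    """A modification hypothesis violates its chemical constraints."""


class ElementTable:
    """Pinned monoisotopic masses: elements, amino-acid residues, constants.

    Residue masses are derived from elemental formulas under this table so
    that a single set of atomic masses underlies every mass printed by the
    package.  ``PROTON`` (mass of H+) is distinct from the hydrogen *atom*
    mass ``H``: m/z arithmetic uses the proton, neutral-molecule hydrogen
    substitutions use the atom.
    """

    #: element symbol -> monoisotopic mass (Da)
    masses = {
        "H": 1.0078250319,
        "C": 12.0,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "P": 30.97376151,
        "S": 31.97207069,
        "Na": 22.98976928,
        "Al": 26.98153853,
        "Fe": 55.93493633,
    }

    #: residue (= amino acid - water) elemental formulas
    residue_formulas = {
        "G": {"C": 2, "H": 3, "N": 1, "O": 1},
        "A": {"C": 3, "H": 5, "N": 1, "O": 1},
        "S": {"C": 3, "H": 5, "N": 1, "O": 2},
        "P": {"C": 5, "H": 7, "N": 1, "O": 1},
        "V": {"C": 5, "H": 9, "N": 1, "O": 1},
        "T": {"C": 4, "H": 7, "N": 1, "O": 2},
        "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
        "L": {"C": 6, "H": 11, "N": 1, "O": 1},
        "I": {"C": 6, "H": 11, "N": 1, "O": 1},
        "N": {"C": 4, "H": 6, "N": 2, "O": 2},
        "D": {"C": 4, "H": 5, "N": 1, "O": 3},
        "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
        "K": {"C": 6, "H": 12, "N": 2, "O": 1},
        "E": {"C": 5, "H": 7, "N": 1, "O": 3},
        "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
        "H": {"C": 6, "H": 7, "N": 3, "O": 1},
        "F": {"C": 9, "H": 9, "N": 1, "O": 1},
        "R": {"C": 6, "H": 12, "N": 4, "O": 1},
        "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
        "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    }

    WATER = 18.0105646
    PROTON = 1.00727646  # H+ (H atom minus electron mass)
    NH3 = masses["N"] + 3 * masses["H"]
    #: HPO3, the phosphoryl group added per chain-extension step
    PHOSPHO = masses["H"] + masses["P"] + 3 * masses["O"]
    #: H3PO4, the full phosphate neutral loss
    PHOSPHORIC = 3 * masses["H"] + masses["P"] + 4 * masses["O"]
    OXIDATION = masses["O"]
    #: metal/Na-for-hydrogen substitutions on a neutral molecule
    FE_SUB = masses["Fe"] - 3 * masses["H"]
    AL_SUB = masses["Al"] - 3 * masses["H"]
    NA_SUB = masses["Na"] - masses["H"]

    @classmethod
    def formula_mass(cls, formula: dict) -> float:
        """Monoisotopic mass of an elemental formula (counts by symbol)."""
        return sum(cls.masses[el] * n for el, n in formula.items())

    @classmethod
    def residue_mass(cls, letter: str) -> float:
        try:
            return _RESIDUE_MASSES[letter]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue letter {letter!r}") from None


_RESIDUE_MASSES = {
    aa: ElementTable.formula_mass(f) for aa, f in ElementTable.residue_formulas.items()
}

#: alias used throughout the package
ELEMENTS = ElementTable


@dataclass(frozen=True, order=True)
class ModComposition:
    """One modification hypothesis and its neutral mass offset.

    Parameters
    ----------
    n_phos:
        Length of the phosphate chain on one Ser/Thr/Tyr site (0-6).
    n_fe, n_al:
        Number of Fe(III)/Al(III) substitutions; each replaces three
        hydrogens of the neutral molecule.  A trivalent metal is only
        hypothesised on a chain able to chelate it, enforced as
        ``n_phos >= 2 * (n_fe + n_al)``.
    n_na:
        Na(I) substitutions, each replacing one hydrogen.
    n_ox:
        Methionine oxidations (0-3).
    """

    n_phos: int = 0
    n_fe: int = 0
    n_al: int = 0
    n_na: int = 0
    n_ox: int = 0

    def __post_init__(self):
        for name in ("n_phos", "n_fe", "n_al", "n_na", "n_ox"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InvalidHypothesisError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_phos > 6:
            raise InvalidHypothesisError("phosphate chain length is limited to 6")
        if self.n_ox > 3:
            raise InvalidHypothesisError("at most 3 Met oxidations")
        if self.n_phos < 2 * (self.n_fe + self.n_al):
            raise InvalidHypothesisError(
                "a trivalent metal adduct requires at least two phosphates per "
                f"metal (n_phos={self.n_phos}, metals={self.n_fe + self.n_al})"
            )

    @property
    def delta_mass(self) -> float:
        """Neutral monoisotopic mass offset of this composition (Da)."""
        t = ElementTable
        return (
            self.n_phos * t.PHOSPHO
            + self.n_fe * t.FE_SUB
            + self.n_al * t.AL_SUB
            + self.n_na * t.NA_SUB
            + self.n_ox * t.OXIDATION
        )

    @property
    def n_components(self) -> int:
        return self.n_phos + self.n_fe + self.n_al + self.n_na + self.n_ox

    @property
    def n_metal(self) -> int:
        return self.n_fe + self.n_al

    def label(self) -> str:
        """Human-readable class label, e.g. ``'3p+Fe'`` or ``'unmodified'``."""
        parts = []
        if self.n_phos:
            parts.append(f"{self.n_phos}p")
        parts.extend(["Fe"] * self.n_fe)
        parts.extend(["Al"] * self.n_al)
        parts.extend(["Na"] * self.n_na)
        if self.n_ox:
            parts.append(f"{self.n_ox}ox")
        return "+".join(parts) if parts else "unmodified"

    def class_key(self) -> tuple:
        """Biological class identity: Fe and Al adducts of a state are pooled."""
        return (self.n_phos, self.n_metal, self.n_ox)


@dataclass
class MatchResult:
    """Hypotheses compatible with an observed delta mass, best first.

    ``hypotheses`` holds ``(ModComposition, signed error Da)`` sorted by
    absolute error, ties broken by fewer total components, then by smaller
    chain length.  Empty when nothing in the space matches.
    """

    observed_delta: float
    tolerance: float
    hypotheses: list = field(default_factory=list)

    @property
    def best(self) -> ModComposition | None:
        return self.hypotheses[0][0] if self.hypotheses else None

    @property
    def best_error(self) -> float | None:
        return self.hypotheses[0][1] if self.hypotheses else None


def peptide_neutral_mass(sequence: str, mods=()) -> float:
    """Neutral monoisotopic mass of a peptide with optional modifications.

    Sum of residue masses plus one water, plus the delta mass of every
    :class:`ModComposition` in ``mods``.
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    total = ElementTable.WATER
    for i, aa in enumerate(sequence):
        if aa not in _RESIDUE_MASSES:
            raise InvalidSequenceError(
                f"unknown residue letter {aa!r} at position {i + 1}"
            )
        total += _RESIDUE_MASSES[aa]
    for comp in mods:
        total += comp.delta_mass
    return total


def composition_delta(comp: ModComposition) -> float:
    """Neutral mass offset of a modification hypothesis (Da)."""
    return comp.delta_mass


def enumerate_hypotheses(
    max_phos: int = 6,
    max_metal: int = 2,
    max_ox: int = 3,
    allow_na: bool = False,
    max_na: int = 2,
) -> list[ModComposition]:
    """Enumerate every admissible :class:`ModComposition` within bounds.

    The space is the cross product of chain lengths 0..``max_phos``,
    Fe/Al substitutions up to ``max_metal`` in total (each requiring two
    chelating phosphates), optional Na substitutions, and 0..``max_ox``
    Met oxidations.  Returned deduplicated and sorted by delta mass.
    """
    if min(max_phos, max_metal, max_ox, max_na) < 0:
        raise ValueError("bounds must be non-negative")
    out = []
    na_range = range(max_na + 1) if allow_na else (0,)
    for n_phos in range(max_phos + 1):
        for n_fe, n_al in itertools.product(range(max_metal + 1), repeat=2):
            if n_fe + n_al > max_metal or n_phos < 2 * (n_fe + n_al):
                continue
            for n_na in na_range:
                for n_ox in range(max_ox + 1):
                    out.append(ModComposition(n_phos, n_fe, n_al, n_na, n_ox))
    out = sorted(set(out), key=lambda c: (c.delta_mass, c.n_components))
    return out


def match_delta(
    observed: float,
    hypothesis_space: list[ModComposition],
    tolerance: float = 0.01,
) -> MatchResult:
    """Match an observed delta mass against a hypothesis space.

    Candidates within ``tolerance`` are ranked by absolute error; ties by
    parsimony (fewest components), then by smaller chain length.  A delta
    nothing explains yields an empty hypothesis list, not an error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    hits = []
    for comp in hypothesis_space:
        err = comp.delta_mass - observed
        if abs(err) <= tolerance:
            hits.append((comp, err))
    hits.sort(key=lambda h: (abs(h[1]), h[0].n_components, h[0].n_phos))
    return MatchResult(observed_delta=observed, tolerance=tolerance, hypotheses=hits)


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated species: ``(M + z * m_proton) / z``."""
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (neutral_mass + charge * ElementTable.PROTON) / charge


def intact_shift(
    comp_before: ModComposition,
    comp_after: ModComposition,
    rounding: bool = False,
) -> float:
    """Intact-mass shift between two modification states.

    With ``rounding`` the shift is reported to the nearest integer, the
    precision at which deconvoluted intact-protein spectra are read
    (e.g. +80 Da per phosphoryl group).
    """
    shift = comp_after.delta_mass - comp_before.delta_mass
    return float(round(shift)) if rounding else shift


#: The open-search offset masses screened in the lysate searches.  Entries
#: the default hypothesis space does not explain (mixed organic adducts,
#: unknowns) carry the class "unassigned"; the matcher reports no-match for
#: them rather than force-fitting.
OPEN_SEARCH_OFFSETS = (
    0.0, 101.947, 103.9256, 105.9816, 122.973, 132.8784, 136.9884, 141.923,
    159.933, 173.9882, 177.9424, 181.9128, 184.0552, 197.8802, 199.8884,
    201.901, 209.0186, 212.845, 216.9552, 226.8986, 228.8408, 230.8544,
    263.8566, 269.8656, 292.8104, 343.823, 361.8338, 372.7767, 389.8042,
    390.788, 423.7912, 452.7431, 527.7141, 585.6209, 79.9666, 93.9798,
    94.0186, 95.9618, 98.0492,
)
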