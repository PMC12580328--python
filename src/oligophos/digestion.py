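"""In-silico tryptic digestion and search-space filtering.

Trypsin cleaves C-terminal of Lys/Arg except when the next residue is
proline.  Peptides are generated with up to ``max_missed`` missed
cleavages and then filtered to the searched length and mass window.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masscalc import InvalidSequenceError, peptide_neutral_mass

__all__ = ["DigestParams", "DigestPeptide", "digest", "filter_search_space"]


@dataclass(frozen=True)
class DigestParams:
    """Digestion and search-space bounds (defaults as searched)."""

    max_missed: int = 2
    min_len: int = 7
    max_len: int = 50
    min_mass: float = 500.0
    max_mass: float = 5000.0

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass must not exceed max_mass")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    neutral_mass: float


def cleavage_sites(protein: str) -> list[int]:
    """0-based indices *after* which trypsin cuts (K/R not followed by P)."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest(protein: str, params: DigestParams = DigestParams()) -> list[DigestPeptide]:
    """All tryptic peptides with 0..max_missed missed cleavages.

    Length/mass filtering is a separate step (:func:`filter_search_space`);
    output is deterministic, ordered by (start, end).
    """
    if not protein:
        raise InvalidSequenceError("empty protein sequence")
    # validates residues as a side effect
    peptide_neutral_mass(protein)

    cuts = cleavage_sites(protein)
    # fragment boundaries: [start, end) pairs of the 0-missed peptides
    bounds = []
    prev = 0
    for c in cuts:
        bounds.append((prev, c + 1))
        prev = c + 1
    bounds.append((prev, len(protein)))

    peptides = []
    for i in range(len(bounds)):
        for missed in range(params.max_missed + 1):
            j = i + missed
            if j >= len(bounds):
                break
            start, end = bounds[i][0], bounds[j][1]
            seq = protein[start:end]
            peptides.append(
                DigestPeptide(
                    sequence=seq,
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                    neutral_mass=peptide_neutral_mass(seq),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def filter_search_space(
    peptides: list[DigestPeptide], params: DigestParams = DigestParams()
) -> list[DigestPeptide]:
    """Retain peptides within the searched length and mass windows."""
    return [
        p
        for p in peptides
        if params.min_len <= len(p.sequence) <= params.max_len
        and params.min_mass <= p.neutral_mass <= params.max_mass
    ]
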