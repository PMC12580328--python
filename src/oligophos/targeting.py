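"""Parallel-reaction-monitoring (PRM) inclusion lists for phospho species.

For targeted validation, every plausible species of a peptide is listed:
phosphorylation states up to tetraphosphorylation, Fe(III)/Al(III) adducts
on states able to chelate them (at least two phosphates per metal), and
Met oxidation, across the instrument's charge range.  Site permutations
collapse to composition level — the precursor m/z does not depend on which
S/T/Y carries the chain.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .masscalc import (
    InvalidHypothesisError,
    ModComposition,
    peptide_neutral_mass,
    precursor_mz,
)

__all__ = ["build_inclusion_list"]

_METAL_FIELD = {"Fe": "n_fe", "Al": "n_al"}


def build_inclusion_list(
    sequences: list[str],
    max_phos: int = 4,
    adducts: tuple[str, ...] = ("Fe", "Al"),
    max_metal: int = 1,
    max_ox: int = 1,
    charges: tuple[int, ...] = (2, 3, 4),
) -> pd.DataFrame:
    """Cross-product of modification states x charges for target peptides.

    Phospho states are skipped for sequences without S/T/Y, oxidation for
    sequences without M.  Output columns: mz, z, label, sequence,
    n_phos, n_fe, n_al, n_ox; sorted by m/z, deduplicated.
    """
    if not sequences:
        raise ValueError("at least one target sequence is required")
    for metal in adducts:
        if metal not in _METAL_FIELD:
            raise InvalidHypothesisError(f"unknown adduct {metal!r}; use Fe and/or Al")

    rows = []
    for seq in sequences:
        peptide_neutral_mass(seq)  # validates
        phos_states = range(max_phos + 1) if any(c in "STY" for c in seq) else (0,)
        ox_states = range(max_ox + 1) if "M" in seq else (0,)
        for n_phos, n_ox in itertools.product(phos_states, ox_states):
            metal_options = [{}]
            for count in range(1, max_metal + 1):
                for combo in itertools.combinations_with_replacement(adducts, count):
                    if n_phos >= 2 * count:
                        fields = {"n_fe": 0, "n_al": 0}
                        for m in combo:
                            fields[_METAL_FIELD[m]] += 1
                        metal_options.append(fields)
            for fields in metal_options:
                comp = ModComposition(n_phos=n_phos, n_ox=n_ox, **fields)
                neutral = peptide_neutral_mass(seq, (comp,))
                for z in charges:
                    rows.append(
                        {
                            "mz": precursor_mz(neutral, z),
                            "z": z,
                            "label": comp.label(),
                            "sequence": seq,
                            "n_phos": comp.n_phos,
                            "n_fe": comp.n_fe,
                            "n_al": comp.n_al,
                            "n_ox": comp.n_ox,
                        }
                    )
    df = pd.DataFrame(rows).drop_duplicates()
    return df.sort_values("mz", kind="stable").reset_index(drop=True)
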