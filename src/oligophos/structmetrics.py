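"""Phosphate-to-histidine distances in atomic coordinate models.

The intramolecular phosphoryl-transfer geometry of NME1 is summarised by
the distance between the terminal atom of the (phospho)Ser/Thr 94 side
chain and the Ndelta1 nitrogen of the catalytic His118 (the nitrogen that
carries the 1-phosphohistidine intermediate).  Models are read from PDB or
mmCIF with gemmi.

Terminal-atom convention per phosphorylation state (the depositions do not
name a canonical pair, so both a phosphorus-based distance and the minimum
over the terminal phosphate oxygens are reported to bracket the value):

===========  =====================================  =================
state        terminal phosphorus atom names tried   fallback
===========  =====================================  =================
wild-type    (none - side-chain terminal O/C atom)  OG1/OG/CG2
mono         P, PA, P1                              farthest P from CB
pyro         PB, P2                                 farthest P from CB
tri          PG, P3                                 farthest P from CB
===========  =====================================  =================
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi

__all__ = [
    "AtomSelection",
    "SelectionError",
    "read_model",
    "atom_distance",
    "site_his_distance",
    "SiteHisDistance",
]


class SelectionError(ValueError):
    """An atom selection resolved to zero or multiple atoms."""


@dataclass(frozen=True)
class AtomSelection:
    """One atom: chain, author residue number, optional residue name, atom name."""

    chain: str
    residue: int
    atom: str
    residue_name: str | None = None

    def __str__(self) -> str:
        rn = f" {self.residue_name}" if self.residue_name else ""
        return f"{self.chain}/{self.residue}{rn}/{self.atom}"


def read_model(path) -> gemmi.Structure:
    """Read a PDB or mmCIF coordinate file (format detected by gemmi)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _resolve(structure: gemmi.Structure, sel: AtomSelection) -> gemmi.Atom:
    matches = []
    model = structure[0]
    for chain in model:
        if chain.name != sel.chain:
            continue
        for residue in chain:
            if residue.seqid.num != sel.residue:
                continue
            if sel.residue_name and residue.name != sel.residue_name:
                continue
            for atom in residue:
                if atom.name == sel.atom:
                    matches.append(atom)
    if not matches:
        raise SelectionError(f"no atom matches selection {sel}")
    if len(matches) > 1:
        raise SelectionError(f"selection {sel} is ambiguous ({len(matches)} atoms)")
    return matches[0]


def atom_distance(model, a: AtomSelection, b: AtomSelection) -> float:
    """Euclidean distance (Angstrom) between two uniquely selected atoms."""
    if not isinstance(model, gemmi.Structure):
        model = read_model(model)
    return _resolve(model, a).pos.dist(_resolve(model, b).pos)


_TERMINAL_P = {
    "mono": ("P", "PA", "P1"),
    "pyro": ("PB", "P2"),
    "tri": ("PG", "P3"),
}
_CHAIN_LENGTH = {"mono": 1, "pyro": 2, "tri": 3}
_WT_TERMINAL = ("OG1", "OG", "CG2")


@dataclass
class SiteHisDistance:
    """Distances from the residue-94 terminus to His118 ND1 (Angstrom)."""

    p_distance: float | None
    p_atom: str | None
    o_min_distance: float | None
    o_atom: str | None
    state: str

    @property
    def distance(self) -> float:
        """The phosphorus-based distance, falling back to the oxygen minimum."""
        return self.p_distance if self.p_distance is not None else self.o_min_distance


def site_his_distance(
    model,
    phospho_state: str,
    chain: str = "A",
    site: int = 94,
    his: int = 118,
    his_atom: str = "ND1",
) -> SiteHisDistance:
    """Distance between the terminal phosphate of residue 94 and His118 N1.

    ``phospho_state`` is one of ``wt``, ``mono``, ``pyro``, ``tri``.  For
    phosphorylated states the terminal phosphorus of the chain is used
    (falling back to the phosphorus farthest from CB when atom names are
    non-standard) together with the minimum over the terminal phosphate
    oxygens; for ``wt`` the side-chain terminal atom of Thr/Ser.
    """
    if not isinstance(model, gemmi.Structure):
        model = read_model(model)
    his_sel = AtomSelection(chain=chain, residue=his, atom=his_atom)
    his_pos = _resolve(model, his_sel).pos

    residue = None
    for ch in model[0]:
        if ch.name != chain:
            continue
        for r in ch:
            if r.seqid.num == site:
                residue = r
                break
    if residue is None:
        raise SelectionError(f"residue {site} not found in chain {chain!r}")

    atoms = {a.name: a for a in residue}

    if phospho_state == "wt":
        for name in _WT_TERMINAL:
            if name in atoms:
                d = atoms[name].pos.dist(his_pos)
                return SiteHisDistance(d, name, None, None, "wt")
        raise SelectionError(f"no side-chain terminal atom found on residue {site}")

    if phospho_state not in _TERMINAL_P:
        raise ValueError(f"unknown phospho_state {phospho_state!r}")

    p_atoms = [a for a in residue if a.element.name == "P"]
    if len(p_atoms) < _CHAIN_LENGTH[phospho_state]:
        raise SelectionError(
            f"residue {site} carries {len(p_atoms)} phosphorus atom(s); "
            f"state {phospho_state!r} expects {_CHAIN_LENGTH[phospho_state]}"
        )
    terminal = None
    for name in _TERMINAL_P[phospho_state]:
        if name in atoms:
            terminal = atoms[name]
            break
    if terminal is None and "CB" in atoms:
        terminal = max(p_atoms, key=lambda a: a.pos.dist(atoms["CB"].pos))
    if terminal is None:
        raise SelectionError(f"cannot identify terminal phosphorus of residue {site}")

    p_distance = terminal.pos.dist(his_pos)
    # terminal phosphate oxygens: O atoms within bonding range of the
    # terminal phosphorus (P-O bonds are ~1.5-1.7 A)
    terminal_o = [
        a
        for a in residue
        if a.element.name == "O" and a.pos.dist(terminal.pos) < 1.8
    ]
    o_min = o_name = None
    if terminal_o:
        best = min(terminal_o, key=lambda a: a.pos.dist(his_pos))
        o_min, o_name = best.pos.dist(his_pos), best.name
    return SiteHisDistance(p_distance, terminal.name, o_min, o_name, phospho_state)
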