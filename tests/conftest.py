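"""Shared fixtures: hypothesis space, simulation configs, synthetic structures."""

from __future__ import annotations

import math

import gemmi
import numpy as np
import pytest

from oligophos.masscalc import enumerate_hypotheses
from oligophos.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def default_space():
    return enumerate_hypotheses()


@pytest.fixture()
def simconfig():
    return SimConfig(seed=1234)


def _add_atom(residue: gemmi.Residue, name: str, element: str, xyz) -> None:
    atom = gemmi.Atom()
    atom.name = name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*xyz)
    atom.occ = 1.0
    atom.b_iso = 20.0
    residue.add_atom(atom)


def build_site_model(state: str, p_his_distance: float) -> gemmi.Structure:
    """Synthetic stand-in active-site model (NOT deposited coordinates).

    Chain A with residue 94 (Thr or phospho-Ser with a phosphate chain of
    the requested length) and His118; the *terminal* chain atom is placed
    exactly ``p_his_distance`` Angstrom from His118 ND1 along +x, with the
    rest of the side chain built further out so the terminal atom is the
    phosphorus farthest from CB.  Used to verify the measurement
    convention where the deposited models cannot be read.
    """
    st = gemmi.Structure()
    st.name = "synthetic-site"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    his = gemmi.Residue()
    his.name = "HIS"
    his.seqid = gemmi.SeqId(118, " ")
    _add_atom(his, "ND1", "N", (0.0, 0.0, 0.0))
    _add_atom(his, "CE1", "C", (-1.3, 0.2, 0.4))
    _add_atom(his, "NE2", "N", (-2.1, -0.6, -0.3))

    res = gemmi.Residue()
    res.seqid = gemmi.SeqId(94, " ")
    d = p_his_distance
    if state == "wt":
        res.name = "THR"
        _add_atom(res, "OG1", "O", (d, 0.0, 0.0))
        _add_atom(res, "CG2", "C", (d + 1.2, 1.0, 0.0))
        _add_atom(res, "CB", "C", (d + 1.5, 0.0, 0.0))
    else:
        res.name = "SEP"
        n_p = {"mono": 1, "pyro": 2, "tri": 3}[state]
        # chain runs toward His118: P1 nearest CB, terminal P at distance d
        for i in range(n_p):
            x = d + 1.6 * (n_p - 1 - i)
            name = ["PA", "PB", "PG"][i] if n_p > 1 else "P"
            _add_atom(res, name, "P", (x, 0.0, 0.0))
            # bridging/terminal oxygens 1.5 A from each P, off-axis so no
            # oxygen is closer to ND1 than the terminal phosphorus
            _add_atom(res, f"O{i + 1}A", "O", (x, 1.5, 0.0))
            _add_atom(res, f"O{i + 1}B", "O", (x, 0.0, 1.5))
        _add_atom(res, "OG", "O", (d + 1.6 * n_p, 0.0, 0.0))
        _add_atom(res, "CB", "C", (d + 1.6 * n_p + 1.4, 0.0, 0.0))
    _add_atom(res, "CA", "C", (d + 8.0, 1.0, 1.0))

    chain.add_residue(res)
    chain.add_residue(his)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture()
def site_model_builder(tmp_path):
    """Write a synthetic stand-in model to disk in PDB or mmCIF form."""

    def _build(state: str, distance: float, fmt: str = "pdb"):
        st = build_site_model(state, distance)
        path = tmp_path / f"synthetic_{state}_{distance:.1f}.{fmt}"
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
        return path

    return _build


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
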