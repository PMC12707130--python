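"""Shared fixtures: all test structures are generated, never stored."""

from __future__ import annotations

import numpy as np
import pytest

from amine_profiler.fixtures import make_helix, make_pair
from amine_profiler.fixtures.bases import base_template
from amine_profiler.geometry import rotation_about_axis
from amine_profiler.structure import AtomRecord, Structure


@pytest.fixture(scope="session")
def helix():
    return make_helix("GGCGCC")


@pytest.fixture(scope="session")
def long_helix():
    return make_helix("GGCGCAUGCGCC", entry_id="HLX2")


@pytest.fixture(scope="session")
def sheared_ga():
    return make_pair("sheared_ga")


@pytest.fixture(scope="session")
def trans_aa():
    return make_pair("trans_aa_hoogsteen")


@pytest.fixture(scope="session")
def wc_gc():
    return make_pair("wc_gc")


def make_atom(name, element, pos, chain="A", resnum=1, resname="G",
              entry="TEST", is_polymer=True):
    return AtomRecord(entry, 1, chain, resname, resnum, "", name, element,
                      np.asarray(pos, float), is_polymer=is_polymer)


def random_structure(seed: int, n_residues: int = 22,
                     box: float = 26.0) -> Structure:
    """Random jumble of nucleotide bases + backbone-oxygen decoys.

    Bases are placed at random rigid transforms inside a cube, giving dense
    random donor/acceptor contact geometry (~500 atoms at the default size).
    """
    rng = np.random.default_rng(seed)
    atoms = []
    bases = ["A", "C", "G", "U"]
    for i in range(1, n_residues + 1):
        name = bases[rng.integers(len(bases))]
        tpl = base_template(name)
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, float(rng.uniform(0, 360)))
        t = rng.uniform(0, box, size=3)
        for atom_name, pos in tpl.items():
            atoms.append(make_atom(atom_name, atom_name[0], R @ pos + t,
                                   resnum=i, resname=name,
                                   entry=f"RND{seed:03d}"))
        # sprinkle backbone acceptors around the residue
        for extra in ("OP1", "O2'"):
            atoms.append(make_atom(extra, "O", t + rng.uniform(-4, 4, size=3),
                                   resnum=i, resname=name,
                                   entry=f"RND{seed:03d}"))
    return Structure(atoms, entry_id=f"RND{seed:03d}")
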