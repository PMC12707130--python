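"""Immutable residue chemistry tables.

The tables enumerate, per canonical residue, the polar donor hydrogens, the
H-bond acceptor atoms with their lone-pair counts, and the exocyclic amine
definition used for hydrogen placement. Lone-pair bookkeeping follows base
chemistry: oxygens accept two H-bonds, unprotonated ring nitrogens one, and
the amine nitrogen accepts none because its lone pair is delocalized into the
ring. Under the internal-chain counting convention (six backbone/sugar
oxygens per ribonucleotide, no terminal hydroxyl protons) the four canonical
ribonucleotides together provide 62 acceptor lone pairs and 12 polar H's.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import yaml

from .errors import NotAnAcceptor, UnknownResidue

__all__ = [
    "AmineSpec",
    "ResidueChemistry",
    "AcceptorLabel",
    "get_chemistry",
    "hbond_capacity",
    "generalize_acceptor",
    "acceptor_lone_pairs",
    "known_residues",
]


@dataclass(frozen=True)
class AmineSpec:
    """Exocyclic amine: the N, its two H names, the attached ring carbon and
    the two in-plane ring anchors that orient sp2 hydrogen placement."""

    nitrogen: str
    hydrogens: tuple[str, str]
    carbon: str
    refs: tuple[str, str]


@dataclass(frozen=True)
class ResidueChemistry:
    residue_name: str
    kind: str  # "rna" | "dna" | "aa"
    letter: str
    amine: AmineSpec | None
    donors: tuple[tuple[str, int], ...]  # (heavy atom, polar H count)
    acceptors: tuple[tuple[str, int], ...]  # (atom, lone-pair count)
    base_atoms: frozenset[str] = field(default_factory=frozenset)

    def acceptor_map(self) -> dict[str, int]:
        return dict(self.acceptors)


@dataclass(frozen=True, order=True)
class AcceptorLabel:
    """Generalized acceptor identity used for pair counting.

    residue_class is the base letter for base atoms, the amino-acid code for
    side chains, "N" for any nucleotide backbone atom and "AA" for the
    peptide backbone; OP1/OP2 are merged to the single "NPO" atom label.
    """

    residue_class: str
    atom_label: str

    def __str__(self) -> str:  # e.g. "N(NPO)", "G(N3)", "AA(O)"
        return f"{self.residue_class}({self.atom_label})"


@lru_cache(maxsize=1)
def _tables() -> dict:
    with importlib.resources.files("amine_profiler.data").joinpath(
        "chemistry.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def _build(residue_name: str, include_sidechain_acceptors: bool) -> ResidueChemistry:
    t = _tables()
    if residue_name in t["nucleotides"]:
        rec = t["nucleotides"][residue_name]
        bb = t["backbone"][rec["kind"]]
        donors = dict(rec.get("base_donors") or {})
        donors.update(bb.get("donors") or {})
        acceptors = dict(rec.get("base_acceptors") or {})
        acceptors.update(bb.get("acceptors") or {})
        amine = None
        if rec.get("amine"):
            a = rec["amine"]
            amine = AmineSpec(
                a["nitrogen"], tuple(a["hydrogens"]), a["carbon"], tuple(a["refs"])
            )
        return ResidueChemistry(
            residue_name=residue_name,
            kind=rec["kind"],
            letter=rec["letter"],
            amine=amine,
            donors=tuple(sorted(donors.items())),
            acceptors=tuple(sorted(acceptors.items())),
            base_atoms=frozenset(rec["base_atoms"]),
        )
    if residue_name in t["amino_acids"]:
        rec = t["amino_acids"][residue_name]
        bb = t["aa_backbone"]
        donors = dict(rec.get("side_donors") or {})
        if residue_name != "PRO":  # proline backbone N has no polar H
            donors.update(bb.get("donors") or {})
        acceptors = dict(rec.get("side_acceptors") or {}) if include_sidechain_acceptors else {}
        acceptors.update(bb.get("acceptors") or {})
        return ResidueChemistry(
            residue_name=residue_name,
            kind="aa",
            letter=residue_name,
            amine=None,
            donors=tuple(sorted(donors.items())),
            acceptors=tuple(sorted(acceptors.items())),
        )
    raise UnknownResidue(residue_name)


@lru_cache(maxsize=None)
def get_chemistry(
    residue_name: str, include_sidechain_acceptors: bool = True
) -> ResidueChemistry:
    """Look up the chemistry entry for a canonical residue code.

    Unknown or modified residue codes raise :class:`UnknownResidue` rather
    than guessing a chemistry.
    """
    return _build(residue_name, include_sidechain_acceptors)


def known_residues() -> frozenset[str]:
    t = _tables()
    return frozenset(t["nucleotides"]) | frozenset(t["amino_acids"])


def hbond_capacity(residue_names, internal: bool = True) -> tuple[int, int]:
    """Sum acceptor lone pairs and donor polar H's over a residue list.

    ``internal=True`` applies the internal-chain convention (six backbone
    oxygens per nucleotide counted, 2'-OH proton counted, no terminal
    hydroxyl protons); ``internal=False`` restricts to base moieties.
    """
    lone_pairs = 0
    polar_h = 0
    t = _tables()
    for name in residue_names:
        chem = get_chemistry(name)
        if internal or chem.kind == "aa":
            lone_pairs += sum(lp for _, lp in chem.acceptors)
            polar_h += sum(nh for _, nh in chem.donors)
        else:
            rec = t["nucleotides"][name]
            lone_pairs += sum((rec.get("base_acceptors") or {}).values())
            polar_h += sum((rec.get("base_donors") or {}).values())
    return lone_pairs, polar_h


_NUC_BACKBONE = {"OP1", "OP2", "O5'", "O4'", "O3'", "O2'"}


def generalize_acceptor(residue_name: str, atom_name: str) -> AcceptorLabel:
    """Map a (residue, atom) acceptor to its generalized counting label.

    OP1/OP2 merge into "NPO"; nucleotide backbone atoms are classed "N";
    the peptide backbone carbonyl oxygen is "AA(O)"; base and side-chain
    atoms keep their residue identity.
    """
    chem = get_chemistry(residue_name)
    if atom_name not in chem.acceptor_map():
        raise NotAnAcceptor(f"{atom_name} is not an acceptor of {residue_name}")
    if chem.kind in ("rna", "dna"):
        if atom_name in ("OP1", "OP2"):
            return AcceptorLabel("N", "NPO")
        if atom_name in _NUC_BACKBONE:
            return AcceptorLabel("N", atom_name)
        return AcceptorLabel(chem.letter, atom_name)
    if atom_name == "O":
        return AcceptorLabel("AA", "O")
    return AcceptorLabel(residue_name, atom_name)


def acceptor_lone_pairs(residue_name: str, atom_name: str) -> int:
    chem = get_chemistry(residue_name)
    try:
        return chem.acceptor_map()[atom_name]
    except KeyError as exc:
        raise NotAnAcceptor(f"{atom_name} is not an acceptor of {residue_name}") from exc
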