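"""Structure I/O and normalization.

Reads mmCIF/PDB via gemmi into a flat list of :class:`AtomRecord`, keeps one
model and one altloc per site, strips hydrogens, places idealized sp2
hydrogens on exocyclic amines, and parses representative-set (nrlist) CSV
listings into IFE selections.

Amine protonation is fully deterministic: both hydrogens are placed in the
base plane at the configured N-H bond length, symmetric about the C-N axis,
one cis and one trans to the first ring anchor.
"""

from __future__ import annotations

import csv
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .errors import GeometryError, ModelNotFound, ParseError
from .geometry import unit

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "AmineSite",
    "IFE",
    "load_structure",
    "strip_hydrogens",
    "protonate_amines",
    "parse_representative_set",
    "fetch_structure",
]

ResidueKey = tuple[str, int, str]  # (chain, residue number, insertion code)


@dataclass
class AtomRecord:
    entry_id: str
    model: int
    chain: str
    residue_name: str
    residue_number: int
    icode: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_polymer: bool = True

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.residue_number, self.icode)


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def chain(self) -> str:
        return self.key[0]

    @property
    def number(self) -> int:
        return self.key[1]

    def get(self, atom_name: str) -> AtomRecord | None:
        return self.atoms.get(atom_name)

    def pos(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].position


class Structure:
    """A normalized single-model structure: a list of atoms plus residue and
    spatial indices (built lazily, invalidated on mutation)."""

    def __init__(self, atoms: list[AtomRecord] | None = None, entry_id: str = "XXXX",
                 model: int = 1, metadata: dict | None = None):
        self.entry_id = entry_id
        self.model = model
        self.atoms: list[AtomRecord] = list(atoms or [])
        self.metadata: dict = dict(metadata or {})
        self._residues: dict[ResidueKey, Residue] | None = None
        self._tree: cKDTree | None = None

    # -- containers ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def add_atom(self, atom: AtomRecord) -> None:
        self.atoms.append(atom)
        self._residues = None
        self._tree = None

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], float)

    @property
    def residues(self) -> dict[ResidueKey, Residue]:
        if self._residues is None:
            res: dict[ResidueKey, Residue] = {}
            for a in self.atoms:
                r = res.get(a.residue_key)
                if r is None:
                    r = res[a.residue_key] = Residue(a.residue_key, a.residue_name)
                r.atoms[a.atom_name] = a
            self._residues = res
        return self._residues

    def chain_residues(self, chain: str) -> list[Residue]:
        """Residues of one chain in (number, icode) order."""
        rs = [r for k, r in self.residues.items() if k[0] == chain]
        rs.sort(key=lambda r: (r.key[1], r.key[2]))
        return rs

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.positions())
        return self._tree

    def copy(self) -> "Structure":
        return Structure([replace(a, position=a.position.copy()) for a in self.atoms],
                         self.entry_id, self.model, dict(self.metadata))

    # -- gemmi conversion ------------------------------------------------
    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.entry_id
        model = gemmi.Model(self.model)
        # group atoms per chain, then per residue in first-seen order
        # (adding to a live gemmi chain invalidates references, so each
        # chain is assembled completely before insertion)
        by_chain: dict[str, dict[ResidueKey, list[AtomRecord]]] = {}
        for a in self.atoms:
            by_chain.setdefault(a.chain, {}).setdefault(a.residue_key, []).append(a)
        for chain_name, residues in by_chain.items():
            ch = gemmi.Chain(chain_name)
            for key, atoms in residues.items():
                res = gemmi.Residue()
                res.name = atoms[0].residue_name
                res.seqid = gemmi.SeqId(atoms[0].residue_number, atoms[0].icode or " ")
                for a in atoms:
                    atom = gemmi.Atom()
                    atom.name = a.atom_name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*map(float, a.position))
                    atom.occ = float(a.occupancy)
                    atom.altloc = a.altloc or "\0"
                    res.add_atom(atom)
                ch.add_residue(res)
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        return st

    def write(self, path: str | Path) -> None:
        """Write PDB or mmCIF depending on the file suffix."""
        path = Path(path)
        st = self.to_gemmi()
        if path.suffix.lower() in (".cif", ".mmcif"):
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))


def _polymer_subchains(st: gemmi.Structure) -> set[str]:
    out = set()
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer:
            out.update(ent.subchains)
    return out


def load_structure(source: str | Path, model_policy: int | str = "first",
                   altloc_policy: str = "occupancy") -> Structure:
    """Read an mmCIF or PDB file into a normalized :class:`Structure`.

    One model is retained (``model_policy``: "first" or an explicit model
    number) and one altloc per atom site (``altloc_policy="occupancy"``:
    highest occupancy, ties broken by altloc character order).
    """
    path = Path(source)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    st.setup_entities()
    polymer_sub = _polymer_subchains(st)

    if model_policy == "first":
        model = st[0]
    else:
        wanted = int(model_policy)
        model = None
        for m in st:
            if m.num == wanted:
                model = m
                break
        if model is None:
            raise ModelNotFound(f"model {wanted} not in {path}")

    entry_id = (st.name or path.stem).upper()
    atoms: list[AtomRecord] = []
    for ch in model:
        for res in ch:
            # canonical residues are always polymer-eligible: synthetic files
            # may carry entity records too sparse for gemmi to classify
            is_poly = (res.subchain in polymer_sub) or (res.name in chem.known_residues())
            # group altlocs per atom name, keep one
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                if len(group) == 1:
                    pick = group[0]
                elif altloc_policy == "occupancy":
                    pick = sorted(group, key=lambda a: (-a.occ, a.altloc))[0]
                elif altloc_policy == "first":
                    pick = group[0]
                else:
                    raise ValueError(f"unknown altloc policy {altloc_policy!r}")
                atoms.append(AtomRecord(
                    entry_id=entry_id,
                    model=model.num,
                    chain=ch.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atom_name=name,
                    element=pick.element.name,
                    position=np.array([pick.pos.x, pick.pos.y, pick.pos.z]),
                    occupancy=pick.occ,
                    altloc=(pick.altloc or "").replace("\0", ""),
                    is_polymer=is_poly,
                ))
    out = Structure(atoms, entry_id=entry_id, model=model.num)
    out.metadata["source"] = str(path)
    out.metadata["model_policy"] = model_policy
    out.metadata["altloc_policy"] = altloc_policy
    return out


def strip_hydrogens(structure: Structure) -> Structure:
    """Return a copy without hydrogen/deuterium atoms (idempotent)."""
    atoms = [replace(a, position=a.position.copy()) for a in structure.atoms
             if a.element not in ("H", "D")]
    out = Structure(atoms, structure.entry_id, structure.model, dict(structure.metadata))
    out.metadata["hydrogens_stripped"] = True
    return out


@dataclass
class AmineSite:
    """One exocyclic amine with its two idealized hydrogens."""

    residue_key: ResidueKey
    residue_name: str
    base_type: str  # A | C | G
    n_atom: AtomRecord
    h_names: tuple[str, str]
    h_positions: np.ndarray  # (2, 3)

    @property
    def n_position(self) -> np.ndarray:
        return self.n_atom.position


@dataclass
class ExcludedResidue:
    residue_key: ResidueKey
    residue_name: str
    reason: str


def place_amine_hydrogens(n_pos, c_pos, ref_pos, bond_length: float = 1.01,
                          hnh_angle: float = 120.0) -> np.ndarray:
    """Idealized in-plane sp2 hydrogen placement.

    Both H's lie in the plane spanned by the C-N bond and the ring anchor,
    at ``bond_length`` from N, symmetric about the C->N axis with an H-N-H
    angle of ``hnh_angle``. Row 0 is trans, row 1 cis to the anchor.
    """
    u = unit(np.asarray(n_pos, float) - c_pos)  # C -> N direction
    w = np.asarray(ref_pos, float) - c_pos
    v_raw = w - np.dot(w, u) * u
    v = unit(v_raw)  # in-plane, pointing to the anchor side
    half = np.radians(hnh_angle / 2.0)
    d_trans = np.cos(half) * u - np.sin(half) * v
    d_cis = np.cos(half) * u + np.sin(half) * v
    n = np.asarray(n_pos, float)
    return np.stack([n + bond_length * d_trans, n + bond_length * d_cis])


def protonate_amines(structure: Structure, target_chains=None,
                     bond_length: float = 1.01, hnh_angle: float = 120.0,
                     ) -> tuple[list[AmineSite], list[ExcludedResidue]]:
    """Place two idealized H's on every A/C/G exocyclic amine.

    Only residues named A, C or G (RNA) in ``target_chains`` (default: all
    chains) are protonated. Residues with a missing amine N or anchor atoms,
    or with a non-H atom within 1.2 A of the N other than its ring carbon
    (a covalent modification), are excluded with a recorded reason.
    """
    chains = set(target_chains) if target_chains is not None else None
    sites: list[AmineSite] = []
    excluded: list[ExcludedResidue] = []
    tree = structure.kdtree() if structure.atoms else None
    for key, res in structure.residues.items():
        if chains is not None and key[0] not in chains:
            continue
        if res.name not in ("A", "C", "G"):
            continue
        spec = chem.get_chemistry(res.name).amine
        n_at = res.get(spec.nitrogen)
        if n_at is None:
            excluded.append(ExcludedResidue(key, res.name, "missing amine nitrogen"))
            continue
        c_at = res.get(spec.carbon)
        refs = [res.get(r) for r in spec.refs]
        if c_at is None or any(r is None for r in refs):
            excluded.append(ExcludedResidue(key, res.name, "missing anchor"))
            continue
        # covalent modification guard: a foreign heavy atom bonded to the N
        near = tree.query_ball_point(n_at.position, 1.2) if tree is not None else []
        modified = False
        for idx in near:
            other = structure.atoms[idx]
            if other is n_at or other is c_at:
                continue
            if other.element not in ("H", "D"):
                modified = True
                break
        if modified:
            excluded.append(ExcludedResidue(key, res.name, "modified amine"))
            continue
        try:
            h_pos = place_amine_hydrogens(n_at.position, c_at.position,
                                          refs[0].position, bond_length, hnh_angle)
        except GeometryError:
            excluded.append(ExcludedResidue(key, res.name, "degenerate anchor geometry"))
            continue
        sites.append(AmineSite(
            residue_key=key,
            residue_name=res.name,
            base_type=res.name,
            n_atom=n_at,
            h_names=spec.hydrogens,
            h_positions=h_pos,
        ))
    return sites, excluded


@dataclass(frozen=True)
class IFE:
    """Integrated functional element: one or more RNA chains of one entry."""

    entry_id: str
    model: int
    chains: tuple[str, ...]

    @classmethod
    def from_token(cls, token: str) -> "IFE":
        parts = [p.strip() for p in token.split("+") if p.strip()]
        if not parts:
            raise ParseError("empty IFE token")
        entry = None
        model = None
        chains = []
        for p in parts:
            fields = p.split("|")
            if len(fields) != 3 or not all(fields):
                raise ParseError(f"malformed IFE token {p!r}")
            pdb_id, model_s, chain = fields
            try:
                m = int(model_s)
            except ValueError as exc:
                raise ParseError(f"non-integer model in {p!r}") from exc
            if entry is None:
                entry, model = pdb_id, m
            elif (pdb_id, m) != (entry, model):
                raise ParseError(f"IFE token mixes entries/models: {token!r}")
            chains.append(chain)
        return cls(entry_id=entry, model=model, chains=tuple(chains))


def parse_representative_set(csv_path: str | Path, ife_column: int = 1) -> list[IFE]:
    """Parse an nrlist-style representative-set CSV into IFE selections.

    Each row carries one representative IFE token (chains joined by "+") in
    ``ife_column`` (default column 1, after the equivalence-class id); rows
    with fewer columns fall back to column 0. Malformed tokens raise
    :class:`ParseError` with the row number.
    """
    out: list[IFE] = []
    with open(csv_path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            token = row[ife_column] if len(row) > ife_column else row[0]
            try:
                out.append(IFE.from_token(token))
            except ParseError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
    return out


def fetch_structure(entry_id: str, directory: str | Path,
                    base_url: str = "https://files.rcsb.org/download") -> Path:
    """Download an mmCIF from the PDB into *directory* (cached).

    Network access is optional; the analysis runs entirely from local files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dest = directory / f"{entry_id.upper()}.cif"
    if not dest.exists():
        url = f"{base_url}/{entry_id.upper()}.cif"
        with urllib.request.urlopen(url) as resp:
            dest.write_bytes(resp.read())
    return dest
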