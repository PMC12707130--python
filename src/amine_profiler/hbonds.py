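"""Geometric H-bond detection and donor classification for exocyclic amines.

An amine donates an H-bond to an acceptor when the H-to-acceptor distance is
at most 2.5 A and the N-H-acceptor angle at least 140 deg (both hydrogens
are tested against every candidate within 4.1 A of the nitrogen). Amines
are then classified:

* non    - no passing bond;
* single - passing bonds that use only one hydrogen, or (in principle) both
  hydrogens sharing one acceptor; multifurcated bonds on one H stay single;
* dual   - both hydrogens donate and at least two distinct acceptor atoms
  are engaged.

Donation scenarios refine the classes: 1 = one bond; 2 = both H's to one
shared acceptor; 3/4 = bi/trifurcation on one H; 5 = one bond per H;
6 = dual with a shared acceptor; 7 = dual with one bifurcated H. Scenarios
2 and 6 are geometrically unreachable under the default criteria (the best
achievable shared-acceptor angle is ~120 deg) but remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .errors import ContractViolation, GeometryError
from .geometry import angle
from .structure import AmineSite, AtomRecord, Structure

__all__ = [
    "HBondCriteria",
    "HBondObservation",
    "DonorClassification",
    "find_candidates",
    "measure",
    "evaluate_amine",
    "classify",
    "acceptor_pair",
    "classify_structure",
    "detect_canonical_gc",
    "geometry_histogram",
    "DEFAULT_HISTOGRAM_EXCLUSIONS",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criteria (distances in A, angles in degrees)."""

    prescreen_radius: float = 4.1
    max_h_acceptor_distance: float = 2.5
    min_nha_angle: float = 140.0
    nh_bond_length: float = 1.01

    def __post_init__(self):
        if min(self.prescreen_radius, self.max_h_acceptor_distance,
               self.min_nha_angle, self.nh_bond_length) <= 0:
            raise ValueError("criteria must be positive")
        if self.prescreen_radius < self.max_h_acceptor_distance + self.nh_bond_length:
            raise ValueError("prescreen radius must cover max distance + N-H length")


@dataclass
class HBondObservation:
    """One (hydrogen, acceptor) measurement."""

    amine: AmineSite
    h_index: int  # 0 or 1
    acceptor: AtomRecord
    label: chem.AcceptorLabel
    distance: float
    angle: float
    passes: bool


@dataclass
class DonorClassification:
    amine: AmineSite
    klass: str  # "non" | "single" | "dual"
    scenario: int | None = None
    acceptor_pair: tuple[chem.AcceptorLabel, chem.AcceptorLabel] | None = None
    same_residue: bool | None = None
    pair_atoms: tuple[AtomRecord, AtomRecord] | None = None
    pair_geometry: tuple[tuple[float, float], tuple[float, float]] | None = None
    n_passing: int = 0
    observations: list[HBondObservation] = field(default_factory=list)


def find_candidates(amine: AmineSite, structure: Structure,
                    criteria: HBondCriteria = HBondCriteria(),
                    exclude_parent_residue: bool = False,
                    brute_force: bool = False) -> list[AtomRecord]:
    """Acceptor-capable polymer atoms within the prescreen radius of the N.

    The parent residue's base-moiety atoms are always excluded; with
    ``exclude_parent_residue`` its sugar/phosphate atoms are dropped too.
    """
    n_pos = amine.n_position
    if brute_force:
        indices = range(len(structure.atoms))
    else:
        indices = structure.kdtree().query_ball_point(n_pos, criteria.prescreen_radius)
    out = []
    for i in indices:
        a = structure.atoms[i]
        if not a.is_polymer:
            continue
        if brute_force and np.linalg.norm(a.position - n_pos) > criteria.prescreen_radius:
            continue
        if a.residue_key == amine.residue_key:
            if exclude_parent_residue:
                continue
            try:
                parent = chem.get_chemistry(a.residue_name)
            except chem.UnknownResidue:  # pragma: no cover - parent is A/C/G
                continue
            if a.atom_name in parent.base_atoms:
                continue
        try:
            rc = chem.get_chemistry(a.residue_name)
        except chem.UnknownResidue:
            continue
        if a.atom_name not in rc.acceptor_map():
            continue
        out.append(a)
    out.sort(key=lambda a: (a.chain, a.residue_number, a.icode, a.atom_name))
    return out


def measure(amine: AmineSite, acceptor_pos) -> list[tuple[float, float]]:
    """(distance, angle) for both hydrogens against one acceptor position.

    Distance is H-to-acceptor; angle is N-H-acceptor with the vertex at H.
    Both are invariant under rigid-body motion of the complex.
    """
    acceptor_pos = np.asarray(acceptor_pos, float)
    out = []
    for h in amine.h_positions:
        d = float(np.linalg.norm(acceptor_pos - h))
        if d < 1e-9:
            raise GeometryError("acceptor coincides with hydrogen")
        out.append((d, angle(amine.n_position, h, acceptor_pos)))
    return out


def evaluate_amine(amine: AmineSite, structure: Structure,
                   criteria: HBondCriteria = HBondCriteria(),
                   exclude_parent_residue: bool = False,
                   brute_force: bool = False) -> list[HBondObservation]:
    """All (hydrogen, candidate) measurements for one amine."""
    obs = []
    for acc in find_candidates(amine, structure, criteria,
                               exclude_parent_residue, brute_force):
        label = chem.generalize_acceptor(acc.residue_name, acc.atom_name)
        for h_idx, (d, a) in enumerate(measure(amine, acc.position)):
            obs.append(HBondObservation(
                amine=amine, h_index=h_idx, acceptor=acc, label=label,
                distance=d, angle=a,
                passes=(d <= criteria.max_h_acceptor_distance
                        and a >= criteria.min_nha_angle),
            ))
    return obs


def _acceptor_id(a: AtomRecord):
    return (a.chain, a.residue_number, a.icode, a.atom_name)


def classify(amine: AmineSite, observations: list[HBondObservation]
             ) -> DonorClassification:
    """Sort one amine into non/single/dual and assign its scenario."""
    passing = [o for o in observations if o.passes]
    h_used = {o.h_index for o in passing}
    acceptors = {_acceptor_id(o.acceptor) for o in passing}
    result = DonorClassification(amine=amine, klass="non",
                                 n_passing=len(passing), observations=observations)
    if not passing:
        return result

    dual = len(h_used) == 2 and len(acceptors) >= 2
    if dual:
        result.klass = "dual"
        shared = {_acceptor_id(o.acceptor) for o in passing if o.h_index == 0} & \
                 {_acceptor_id(o.acceptor) for o in passing if o.h_index == 1}
        per_h_counts = [sum(1 for o in passing if o.h_index == h) for h in (0, 1)]
        if shared:
            result.scenario = 6
        elif max(per_h_counts) >= 2:
            result.scenario = 7
        else:
            result.scenario = 5
        pair = acceptor_pair(amine, passing)
        result.acceptor_pair = pair[0]
        result.same_residue = pair[1]
        result.pair_atoms = pair[2]
        result.pair_geometry = pair[3]
        return result

    result.klass = "single"
    if len(passing) == 1:
        result.scenario = 1
    elif len(h_used) == 2:  # both H's, necessarily one shared acceptor
        result.scenario = 2
    elif len(passing) == 2:
        result.scenario = 3
    else:
        result.scenario = 4
    return result


def acceptor_pair(amine: AmineSite, passing: list[HBondObservation]):
    """The dual amine's acceptor pair.

    Per hydrogen the passing acceptor with the greatest angle is kept; when
    both hydrogens elect the same atom, the assignment falls back to the
    distinct-atom combination maximizing the summed angle, which preserves
    the two-acceptor definition of dual donation. The returned pair is
    canonically ordered by label (then by atom identity) for counting.
    """
    by_h = {0: [o for o in passing if o.h_index == 0],
            1: [o for o in passing if o.h_index == 1]}
    if not by_h[0] or not by_h[1]:
        raise ContractViolation("acceptor_pair requires a dual classification")
    best = None
    for o0 in by_h[0]:
        for o1 in by_h[1]:
            if _acceptor_id(o0.acceptor) == _acceptor_id(o1.acceptor):
                continue
            score = o0.angle + o1.angle
            if best is None or score > best[0] + 1e-12:
                best = (score, o0, o1)
    if best is None:
        raise ContractViolation("no distinct acceptor combination available")
    _, o0, o1 = best
    chosen = sorted([o0, o1], key=lambda o: (str(o.label), _acceptor_id(o.acceptor)))
    labels = (chosen[0].label, chosen[1].label)
    same_residue = (o0.acceptor.residue_key == o1.acceptor.residue_key)
    atoms = (chosen[0].acceptor, chosen[1].acceptor)
    geometry = ((chosen[0].distance, chosen[0].angle),
                (chosen[1].distance, chosen[1].angle))
    return labels, same_residue, atoms, geometry


def classify_structure(structure: Structure, sites: list[AmineSite],
                       criteria: HBondCriteria = HBondCriteria(),
                       exclude_parent_residue: bool = False,
                       brute_force: bool = False) -> list[DonorClassification]:
    """Classify every protonated amine of a structure."""
    return [
        classify(site, evaluate_amine(site, structure, criteria,
                                      exclude_parent_residue, brute_force))
        for site in sites
    ]


def detect_canonical_gc(structure: Structure,
                        classifications: list[DonorClassification]
                        ) -> set[tuple]:
    """Canonical GC pairs: both G(N2)->C(O2) and C(N4)->G(O6) bonds pass.

    Returns {(G residue key, C residue key), ...}.
    """
    g_to_c: set[tuple] = set()
    c_to_g: set[tuple] = set()
    for cl in classifications:
        for o in cl.observations:
            if not o.passes:
                continue
            if (cl.amine.base_type == "G" and o.acceptor.residue_name == "C"
                    and o.acceptor.atom_name == "O2"):
                g_to_c.add((cl.amine.residue_key, o.acceptor.residue_key))
            if (cl.amine.base_type == "C" and o.acceptor.residue_name == "G"
                    and o.acceptor.atom_name == "O6"):
                c_to_g.add((o.acceptor.residue_key, cl.amine.residue_key))
    return g_to_c & c_to_g


# amine-acceptor pair types dominated by canonical base-pairing, excluded
# from the criteria-selection heat map (and only there)
DEFAULT_HISTOGRAM_EXCLUSIONS = frozenset({
    ("A", "U(O4)"), ("C", "G(O6)"), ("G", "C(O2)"), ("G", "C(N3)"),
})


def geometry_histogram(classifications: list[DonorClassification],
                       exclusions=DEFAULT_HISTOGRAM_EXCLUSIONS,
                       d_range=(0.0, 4.5), a_range=(0.0, 180.0),
                       d_bin: float = 0.05, a_bin: float = 2.0):
    """2-D (distance, angle) counts over all measured amine-acceptor pairs.

    Per amine-acceptor pair only the hydrogen with the greater N-H-acceptor
    angle contributes one measurement. ``exclusions`` drops the canonical
    base-pair interactions from this plot only; classification never
    excludes them.

    Returns (counts, d_edges, a_edges).
    """
    ds, angs = [], []
    for cl in classifications:
        by_acceptor: dict[tuple, list[HBondObservation]] = {}
        for o in cl.observations:
            by_acceptor.setdefault(_acceptor_id(o.acceptor), []).append(o)
        for obs in by_acceptor.values():
            best = max(obs, key=lambda o: o.angle)
            if (cl.amine.base_type, str(best.label)) in exclusions:
                continue
            ds.append(best.distance)
            angs.append(best.angle)
    d_edges = np.arange(d_range[0], d_range[1] + d_bin / 2, d_bin)
    a_edges = np.arange(a_range[0], a_range[1] + a_bin / 2, a_bin)
    counts, _, _ = np.histogram2d(ds, angs, bins=[d_edges, a_edges])
    return counts, d_edges, a_edges
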