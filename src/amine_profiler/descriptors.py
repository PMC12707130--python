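"""Per-amine burial and conformation descriptors.

* SASA of the amine nitrogen by Shrake-Rupley sphere-point sampling
  (probe 1.40 A, 100 points, Bondi-style van der Waals radii) on the
  hydrogen-free structure.
* Heavy-atom densities in two regions of interest centered on the N:
  ROI 1 is the sphere r <= 7.5 A, ROI 2 the shell 7.5 < r <= 12.5 A
  (closed outer boundaries); densities are atoms/nm^3 over polymer heavy
  atoms only, and the central N itself counts in ROI 1.
* Glycosidic chi (O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for
  pyrimidines), reported in (-180, 180]; syn means chi in (-90, 90), the
  minor population window is (-20, 130).
* Backbone pseudotorsions eta = C4'(i-1)-P(i)-C4'(i)-P(i+1) and
  theta = P(i)-C4'(i)-P(i+1)-C4'(i+1), mapped to [0, 360); undefined at
  termini and across chain breaks, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructure
from .geometry import dihedral
from .structure import Residue, Structure

__all__ = [
    "VDW_RADII",
    "sphere_points",
    "shrake_rupley_sasa",
    "sasa_of_amine_nitrogens",
    "shell_density",
    "chi",
    "is_syn",
    "is_minor",
    "eta_theta",
    "chain_eta_theta",
    "RegionBox",
    "LOCATION_1",
    "LOCATION_2",
    "A_FORM_BOX",
    "in_region",
]

# Bondi-style van der Waals radii (A); unlisted elements fall back to 1.70
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
             "S": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85}
_DEFAULT_RADIUS = 1.70

ROI1_RADIUS = 7.5  # A
ROI2_RADIUS = 12.5  # A
_NM3 = 1e-3  # A^3 -> nm^3
ROI1_VOLUME_NM3 = 4.0 / 3.0 * np.pi * ROI1_RADIUS**3 * _NM3
ROI2_VOLUME_NM3 = 4.0 / 3.0 * np.pi * (ROI2_RADIUS**3 - ROI1_RADIUS**3) * _NM3


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(structure: Structure, indices=None, probe: float = 1.40,
                       n_points: int = 100) -> np.ndarray:
    """Shrake-Rupley SASA (A^2) for the selected atom indices.

    Each atom's solvent sphere (vdW radius + probe) is sampled with
    ``n_points`` spiral points; a point is accessible when outside every
    neighbor's solvent sphere. Deterministic for a fixed point count.
    """
    if not structure.atoms:
        raise EmptyStructure("SASA of an empty structure")
    pos = structure.positions()
    radii = np.array([VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS)
                      for a in structure.atoms])
    solv = radii + probe
    if indices is None:
        indices = range(len(structure.atoms))
    pts = sphere_points(n_points)
    tree = structure.kdtree()
    max_solv = float(solv.max())
    indices = list(indices)
    out = np.zeros(len(indices))
    for j, i in enumerate(indices):
        r_i = solv[i]
        neigh = [k for k in tree.query_ball_point(pos[i], r_i + max_solv) if k != i]
        surface = pos[i] + r_i * pts
        if neigh:
            npos = pos[neigh]
            nr = solv[np.array(neigh)]
            d2 = ((surface[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (nr**2)[None, :] - 1e-9).all(axis=1)
        else:
            accessible = np.ones(n_points, bool)
        out[j] = 4.0 * np.pi * r_i**2 * accessible.mean()
    return out


def sasa_of_amine_nitrogens(structure: Structure, sites, probe: float = 1.40,
                            n_points: int = 100) -> dict:
    """SASA per amine nitrogen, keyed by residue key.

    The structure must already be hydrogen-free (placed amine H's are not
    part of the structure and never occlude the calculation).
    """
    index_of = {id(a): i for i, a in enumerate(structure.atoms)}
    indices = [index_of[id(s.n_atom)] for s in sites]
    values = shrake_rupley_sasa(structure, indices, probe, n_points)
    return {s.residue_key: float(v) for s, v in zip(sites, values)}


def shell_density(structure: Structure, center, r1: float = ROI1_RADIUS,
                  r2: float = ROI2_RADIUS) -> tuple[float, float]:
    """Heavy-atom densities (atoms/nm^3) in the two ROIs around ``center``.

    Counts polymer heavy atoms only; both boundaries are closed on the
    outer edge (r <= r1; r1 < r <= r2).
    """
    center = np.asarray(center, float)
    v1 = 4.0 / 3.0 * np.pi * r1**3 * _NM3
    v2 = 4.0 / 3.0 * np.pi * (r2**3 - r1**3) * _NM3
    n1 = n2 = 0
    for i in structure.kdtree().query_ball_point(center, r2):
        a = structure.atoms[i]
        if a.element in ("H", "D") or not a.is_polymer:
            continue
        r = float(np.linalg.norm(a.position - center))
        if r <= r1:
            n1 += 1
        elif r <= r2:
            n2 += 1
    return n1 / v1, n2 / v2


_PURINES = {"A", "G", "DA", "DG"}
_CHI_ATOMS_PURINE = ("O4'", "C1'", "N9", "C4")
_CHI_ATOMS_PYRIMIDINE = ("O4'", "C1'", "N1", "C2")


def chi(residue: Residue) -> float | None:
    """Glycosidic torsion in (-180, 180]; None when an atom is missing."""
    names = _CHI_ATOMS_PURINE if residue.name in _PURINES else _CHI_ATOMS_PYRIMIDINE
    atoms = [residue.get(n) for n in names]
    if any(a is None for a in atoms):
        return None
    return dihedral(*[a.position for a in atoms])


def is_syn(chi_value: float | None) -> bool:
    """syn conformation: chi strictly inside (-90, 90)."""
    return chi_value is not None and -90.0 < chi_value < 90.0


def is_minor(chi_value: float | None) -> bool:
    """Minor chi population: the (-20, 130) display window."""
    return chi_value is not None and -20.0 < chi_value < 130.0


def _linked(upstream: Residue | None, downstream: Residue | None,
            max_link: float = 2.5) -> bool:
    """Covalent continuity test between consecutive residues.

    Primary rule: O3'(i-1)-P(i) within ``max_link`` A. When O3' is absent
    the C4'(i-1)-P(i) virtual distance (< 7 A) is used instead.
    """
    if upstream is None or downstream is None:
        return False
    p = downstream.get("P")
    if p is None:
        return False
    o3 = upstream.get("O3'")
    if o3 is not None:
        return float(np.linalg.norm(p.position - o3.position)) <= max_link
    c4 = upstream.get("C4'")
    if c4 is None:
        return False
    return float(np.linalg.norm(p.position - c4.position)) <= 7.0


def eta_theta(prev: Residue | None, res: Residue, nxt: Residue | None,
              nxt2: Residue | None = None) -> tuple[float | None, float | None]:
    """(eta, theta) pseudotorsions of ``res`` in [0, 360), None if undefined.

    eta needs C4'(i-1), P(i), C4'(i), P(i+1); theta needs P(i), C4'(i),
    P(i+1), C4'(i+1). Chain termini and chain breaks leave the affected
    torsion undefined.
    """
    def pos(r, name):
        a = r.get(name) if r is not None else None
        return None if a is None else a.position

    eta = theta = None
    p_i, c4_i = pos(res, "P"), pos(res, "C4'")
    if _linked(prev, res) and _linked(res, nxt):
        parts = (pos(prev, "C4'"), p_i, c4_i, pos(nxt, "P"))
        if all(p is not None for p in parts):
            eta = dihedral(*parts) % 360.0
    if _linked(res, nxt):
        parts = (p_i, c4_i, pos(nxt, "P"), pos(nxt, "C4'"))
        if all(p is not None for p in parts):
            theta = dihedral(*parts) % 360.0
    return eta, theta


def chain_eta_theta(structure: Structure, chain: str) -> dict:
    """(eta, theta) for every residue of one chain, keyed by residue key."""
    rs = structure.chain_residues(chain)
    out = {}
    for i, r in enumerate(rs):
        prev = rs[i - 1] if i > 0 else None
        nxt = rs[i + 1] if i + 1 < len(rs) else None
        out[r.key] = eta_theta(prev, r, nxt)
    return out


@dataclass(frozen=True)
class RegionBox:
    """Inclusive rectangular region in the (eta, theta) plane."""

    name: str
    eta_range: tuple[float, float]
    theta_range: tuple[float, float]


LOCATION_1 = RegionBox("location1", (43.0, 72.0), (151.0, 180.0))
LOCATION_2 = RegionBox("location2", (295.0, 324.0), (14.0, 43.0))
A_FORM_BOX = RegionBox("a_form", (145.0, 190.0), (190.0, 245.0))


def in_region(eta: float | None, theta: float | None, box: RegionBox) -> bool:
    """Inclusive membership; undefined torsions are never inside."""
    if eta is None or theta is None:
        return False
    return (box.eta_range[0] <= eta <= box.eta_range[1]
            and box.theta_range[0] <= theta <= box.theta_range[1])
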