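"""Planar nucleobase templates and Watson-Crick pair assembly.

Bases are built as regular polygons (hexagon side 1.38 A, fused regular
pentagon for purines) with exocyclic substituents on outward ring bisectors.
This is idealized rather than crystallographic geometry: it is chemically
plausible, exactly planar, and sufficient for every quantity the package
measures (H placement anchors, donor/acceptor geometry, glycosidic atoms,
coarse-grained fragment atoms).

Watson-Crick pairs are assembled by least-squares fitting an in-plane rigid
transform of the partner base so that each defining H-bond is near-linear at
a 2.0 A H-to-acceptor distance; the builder verifies that every defining
bond passes the default criteria (<=2.5 A, >=140 deg).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from ..chem import get_chemistry
from ..geometry import angle, rotation_about_axis, unit
from ..structure import place_amine_hydrogens

RING_BOND = 1.38
C_O_BOND = 1.23
C_N_BOND = 1.34
GLYCOSIDIC_BOND = 1.47
RING_NH_BOND = 1.01

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]
PURINE_PENTAGON = ["C4", "C5", "N7", "C8", "N9"]


def _regular_polygon_from_edge(p0, p1, n_sides, side_sign):
    """Walk a regular polygon from a directed edge p0->p1; returns vertices
    in walking order starting at p0. side_sign picks the turning side."""
    pts = [np.asarray(p0, float), np.asarray(p1, float)]
    turn = side_sign * (360.0 / n_sides)
    Rz = rotation_about_axis([0, 0, 1], turn)
    edge = pts[1] - pts[0]
    for _ in range(n_sides - 2):
        edge = Rz @ edge
        pts.append(pts[-1] + edge)
    return pts


@lru_cache(maxsize=None)
def base_template(base: str) -> dict[str, np.ndarray]:
    """Atom positions (z=0 plane) for one base plus its glycosidic C1'."""
    if base not in ("A", "C", "G", "U"):
        raise ValueError(f"unsupported base {base!r}")
    coords: dict[str, np.ndarray] = {}
    # hexagon, counterclockwise, N1 pointing "down"
    hexagon = {}
    for k, name in enumerate(PYRIMIDINE_RING):
        a = np.radians(-90.0 + 60.0 * k)
        hexagon[name] = RING_BOND * np.array([np.cos(a), np.sin(a), 0.0])
    coords.update(hexagon)
    hex_centroid = np.mean(list(hexagon.values()), axis=0)

    purine = base in ("A", "G")
    if purine:
        # fused pentagon on the C4-C5 edge, away from the hexagon center
        for sign in (1.0, -1.0):
            ring = _regular_polygon_from_edge(coords["C4"], coords["C5"], 5, sign)
            centroid = np.mean(ring, axis=0)
            if np.linalg.norm(centroid - hex_centroid) > 1.0:
                break
        c4, c5, n7, c8, n9 = ring
        coords["N7"], coords["C8"], coords["N9"] = n7, c8, n9
        pent_centroid = np.mean(ring, axis=0)

    def outward(atom: str, ring_centroid) -> np.ndarray:
        return unit(coords[atom] - ring_centroid)

    if base == "A":
        coords["N6"] = coords["C6"] + C_N_BOND * outward("C6", hex_centroid)
        coords["C1'"] = coords["N9"] + GLYCOSIDIC_BOND * outward("N9", pent_centroid)
    elif base == "G":
        coords["O6"] = coords["C6"] + C_O_BOND * outward("C6", hex_centroid)
        coords["N2"] = coords["C2"] + C_N_BOND * outward("C2", hex_centroid)
        coords["C1'"] = coords["N9"] + GLYCOSIDIC_BOND * outward("N9", pent_centroid)
    elif base == "C":
        coords["O2"] = coords["C2"] + C_O_BOND * outward("C2", hex_centroid)
        coords["N4"] = coords["C4"] + C_N_BOND * outward("C4", hex_centroid)
        coords["C1'"] = coords["N1"] + GLYCOSIDIC_BOND * outward("N1", hex_centroid)
    else:  # U
        coords["O2"] = coords["C2"] + C_O_BOND * outward("C2", hex_centroid)
        coords["O4"] = coords["C4"] + C_O_BOND * outward("C4", hex_centroid)
        coords["C1'"] = coords["N1"] + GLYCOSIDIC_BOND * outward("N1", hex_centroid)
    return {k: v.copy() for k, v in coords.items()}


def ring_centroid(base: str) -> np.ndarray:
    t = base_template(base)
    return np.mean([t[n] for n in PYRIMIDINE_RING], axis=0)


def ring_nh_position(base: str, coords: dict[str, np.ndarray], nitrogen: str) -> np.ndarray:
    """Idealized ring N-H along the outward hexagon bisector."""
    centroid = np.mean([coords[n] for n in PYRIMIDINE_RING], axis=0)
    return coords[nitrogen] + RING_NH_BOND * unit(coords[nitrogen] - centroid)


def amine_h_positions(base: str, coords: dict[str, np.ndarray]) -> np.ndarray:
    """(2, 3) amine hydrogens for a base template (row 0 trans, 1 cis to
    the first ring anchor, i.e. the Watson-Crick-edge hydrogen is row 1)."""
    spec = get_chemistry(base).amine
    return place_amine_hydrogens(coords[spec.nitrogen], coords[spec.carbon],
                                 coords[spec.refs[0]])


# Defining H-bonds per unordered Watson-Crick pair. Donor entries:
# (donor base, "amine_cis" | ring nitrogen name, acceptor base, acceptor atom)
_WC_BONDS = {
    frozenset(("G", "C")): [
        ("G", "N1", "C", "N3"),
        ("G", "amine_cis", "C", "O2"),
        ("C", "amine_cis", "G", "O6"),
    ],
    frozenset(("A", "U")): [
        ("A", "amine_cis", "U", "O4"),
        ("U", "N3", "A", "N1"),
    ],
}

_H_TO_ACCEPTOR = 2.0  # target H...acceptor distance for ideal bonds


def _donor_geometry(base: str, coords: dict[str, np.ndarray], kind: str):
    """Return (heavy donor position, H position) for one defining bond."""
    if kind == "amine_cis":
        spec = get_chemistry(base).amine
        h = amine_h_positions(base, coords)[1]
        return coords[spec.nitrogen], h
    return coords[kind], ring_nh_position(base, coords, kind)


def _apply_inplane(coords: dict[str, np.ndarray], theta_deg, tx, ty):
    R = rotation_about_axis([0, 0, 1], theta_deg)
    t = np.array([tx, ty, 0.0])
    return {k: R @ v + t for k, v in coords.items()}


@lru_cache(maxsize=None)
def pair_template(base1: str, base2: str) -> tuple[dict, dict]:
    """Coplanar Watson-Crick pair (base1 fixed, base2 fitted).

    Returns the two coordinate dicts in a canonical frame: C1'-C1' axis
    along y (base1 on -y), midpoint on the +x axis at the helical
    displacement used by the duplex generator.
    """
    if COMPLEMENT[base1] != base2:
        raise ValueError(f"{base1}-{base2} is not a Watson-Crick combination")
    bonds = _WC_BONDS[frozenset((base1, base2))]
    fixed = base_template(base1)
    mobile0 = base_template(base2)

    def residuals(params):
        mobile = _apply_inplane(mobile0, *params)
        res = []
        for donor, kind, acc_base, acc_atom in bonds:
            if donor == base1:
                heavy, h = _donor_geometry(base1, fixed, kind)
                target = h + _H_TO_ACCEPTOR * unit(h - heavy)
                res.extend((mobile[acc_atom] - target)[:2])
            else:
                heavy, h = _donor_geometry(base2, mobile, kind)
                target = h + _H_TO_ACCEPTOR * unit(h - heavy)
                res.extend((fixed[acc_atom] - target)[:2])
        return res

    best = None
    for theta0 in (180.0, 120.0, 240.0, 0.0):
        guess = [theta0, 5.0, 0.0]
        sol = least_squares(residuals, guess, method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    mobile = _apply_inplane(mobile0, *best.x)

    # verify the defining bonds against the default criteria
    both = {base1: fixed, base2: mobile}
    for donor, kind, acc_base, acc_atom in bonds:
        heavy, h = _donor_geometry(donor, both[donor], kind)
        acc = both[acc_base][acc_atom]
        d = float(np.linalg.norm(acc - h))
        a = angle(heavy, h, acc)
        if d > 2.5 or a < 140.0:
            raise RuntimeError(
                f"pair template {base1}-{base2}: bond {donor}->{acc_atom} "
                f"failed ({d:.2f} A, {a:.1f} deg)")

    # canonical frame: C1'(1) -> C1'(2) along +y, midpoint at (disp, 0, 0)
    disp = 8.0  # base-pair displacement from the helical axis
    c1a, c1b = fixed["C1'"], mobile["C1'"]
    mid = 0.5 * (c1a + c1b)
    yaxis = unit(c1b - c1a)
    th = np.degrees(np.arctan2(yaxis[1], yaxis[0]))
    R = rotation_about_axis([0, 0, 1], 90.0 - th)

    def to_frame(coords):
        return {k: R @ (v - mid) + np.array([disp, 0.0, 0.0]) for k, v in coords.items()}

    f1, f2 = to_frame(fixed), to_frame(mobile)
    # bases must point inward (toward the axis at the origin)
    centroid = np.mean([f1[n] for n in PYRIMIDINE_RING], axis=0)
    if centroid[0] > disp:
        flip = rotation_about_axis([0, 1, 0], 180.0)
        off = np.array([disp, 0.0, 0.0])
        f1 = {k: flip @ (v - off) + off for k, v in f1.items()}
        f2 = {k: flip @ (v - off) + off for k, v in f2.items()}
    return f1, f2
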