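"""Small vector-geometry primitives: angles, dihedrals, superposition.

All positions are (3,) or (n, 3) float arrays in Angstroms; angles are in
degrees unless noted.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raise on (near-)zero length."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees within [0, 180]."""
    u = unit(np.asarray(a, float) - b)
    w = unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable near 0/180.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    if ang > 180.0:
        ang -= 360.0
    return ang


def rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotation matrix about *axis* by theta (Rodrigues)."""
    k = unit(np.asarray(axis, float))
    t = np.radians(theta_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to c with |D-c|=bond, angle(D,c,b)=angle_deg and
    dihedral(D,c,b,a)=torsion_deg (natural extension reference frame)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal proper-rotation superposition of *mobile* onto *target*.

    Returns (rmsd, transformed_mobile). Reflections are excluded by the
    determinant guard, so enantiomers do not superpose to zero.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("point sets must share an (n, 3) shape")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (R @ P0.T).T + qc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return rmsd, moved


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal superposition RMSD between two equal-size point sets."""
    return kabsch_superpose(a, b)[0]
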