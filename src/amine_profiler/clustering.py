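"""Fragment extraction and superposition-RMSD clustering for motif discovery.

Around a residue of interest and its base-pairing partner a 6 x 5 nucleotide
fragment is cut (strand 1: two residues upstream through three downstream of
the residue of interest; strand 2: partner +/- 2), coarse-grained to five
atoms per nucleotide (P, C4', N9, C2, C6 for purines; P, C4', N1, C2, C4
for pyrimidines). All-vs-all minimal superposition RMSDs (proper rotations
only) feed average-linkage agglomerative clustering; the RMSD cutoff is
scanned from the first value producing a cluster of four or more members up
to the integer below the largest distance, scored with Silhouette,
Calinski-Harabasz and Davies-Bouldin, and chosen by the Silhouette optimum.
Each cluster's representative is the member closest to the cluster's mean
coarse-grained coordinates after superposition onto the cluster medoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .errors import ContractViolation, FragmentIncomplete, NoValidCutoff
from .geometry import kabsch_rmsd, kabsch_superpose
from .structure import Residue, ResidueKey, Structure

__all__ = [
    "COARSE_ATOMS_PURINE",
    "COARSE_ATOMS_PYRIMIDINE",
    "Fragment",
    "ClusterResult",
    "extract_fragment",
    "rmsd_matrix",
    "scan_and_cluster",
    "representative",
    "linkage_to_newick",
]

COARSE_ATOMS_PURINE = ("P", "C4'", "N9", "C2", "C6")
COARSE_ATOMS_PYRIMIDINE = ("P", "C4'", "N1", "C2", "C4")
_PURINES = {"A", "G", "DA", "DG"}

STRAND1_OFFSETS = (-2, 3)  # residue of interest at position 3 of 6
STRAND2_OFFSETS = (-2, 2)  # partner centered


@dataclass
class Fragment:
    """One coarse-grained 6x5-nt fragment (55 points when complete)."""

    source: str
    roi_key: ResidueKey
    strand1_keys: tuple[ResidueKey, ...]
    strand2_keys: tuple[ResidueKey, ...]
    coords: np.ndarray  # (55, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)


def _coarse_atoms(residue: Residue) -> list[np.ndarray]:
    names = COARSE_ATOMS_PURINE if residue.name in _PURINES else COARSE_ATOMS_PYRIMIDINE
    pts = []
    for n in names:
        a = residue.get(n)
        if a is None:
            raise FragmentIncomplete(
                f"residue {residue.key} lacks coarse-grain atom {n}")
        pts.append(a.position)
    return pts


def _window(residues: list[Residue], index: int, offsets: tuple[int, int]
            ) -> list[Residue]:
    lo, hi = index + offsets[0], index + offsets[1]
    if lo < 0 or hi >= len(residues):
        raise FragmentIncomplete("window extends past the chain terminus")
    return residues[lo:hi + 1]


def extract_fragment(structure: Structure, roi_key: ResidueKey,
                     partner_key: ResidueKey,
                     strand1_offsets: tuple[int, int] = STRAND1_OFFSETS,
                     strand2_offsets: tuple[int, int] = STRAND2_OFFSETS
                     ) -> Fragment:
    """Cut the coarse-grained fragment around a residue and its partner.

    Incomplete windows (missing flanks or coarse-grain atoms) raise
    :class:`FragmentIncomplete`; fragments are never padded.
    """
    def locate(key):
        rs = structure.chain_residues(key[0])
        for i, r in enumerate(rs):
            if r.key == key:
                return rs, i
        raise FragmentIncomplete(f"residue {key} not found")

    rs1, i1 = locate(roi_key)
    rs2, i2 = locate(partner_key)
    strand1 = _window(rs1, i1, strand1_offsets)
    strand2 = _window(rs2, i2, strand2_offsets)
    pts = []
    for r in strand1 + strand2:
        pts.extend(_coarse_atoms(r))
    return Fragment(
        source=structure.entry_id,
        roi_key=roi_key,
        strand1_keys=tuple(r.key for r in strand1),
        strand2_keys=tuple(r.key for r in strand2),
        coords=np.array(pts),
    )


def rmsd_matrix(fragments: list[Fragment]) -> np.ndarray:
    """Symmetric all-vs-all minimal superposition RMSD matrix (A)."""
    n = len(fragments)
    counts = {f.coords.shape for f in fragments}
    if len(counts) > 1:
        raise ContractViolation(f"fragments differ in point count: {counts}")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(fragments[i].coords, fragments[j].coords)
    return m


@dataclass
class ClusterResult:
    matrix: np.ndarray
    linkage_method: str
    cutoffs: np.ndarray
    metrics: pd.DataFrame  # columns: cutoff, n_clusters, silhouette, ch, db
    cutoff: float
    labels: np.ndarray
    dominant: int
    representatives: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def scan_and_cluster(matrix: np.ndarray, linkage: str = "average",
                     grid_step: float = 0.05, min_cluster_size: int = 4
                     ) -> ClusterResult:
    """Agglomerative clustering with a validation-metric cutoff scan.

    The scan runs from the smallest grid cutoff at which some cluster
    reaches ``min_cluster_size`` members up to the integer below the largest
    pairwise distance; the reported cutoff maximizes the Silhouette score
    (ties to the smaller cutoff). When no scanned cutoff admits a valid
    Silhouette (e.g. everything merges into one cluster immediately), the
    single-cluster labeling at the scan floor is returned.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if n < 2:
        raise NoValidCutoff("need at least two fragments")
    condensed = squareform(matrix, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)

    max_d = float(matrix.max())
    hi = float(np.floor(max_d))
    if hi == max_d:
        hi -= grid_step
    hi = max(hi, 0.0)  # degenerate: identical fragments merge at zero
    grid_all = np.arange(0.0, hi + grid_step / 2, grid_step)
    lo = None
    for c in grid_all:
        labels = hierarchy.fcluster(Z, t=c + 1e-9, criterion="distance")
        if np.bincount(labels).max() >= min_cluster_size:
            lo = c
            break
    if lo is None or lo > hi:
        raise NoValidCutoff("no cutoff in range forms a sufficient cluster")
    cutoffs = np.arange(lo, hi + grid_step / 2, grid_step)

    rows = []
    labelings = {}
    for c in cutoffs:
        labels = hierarchy.fcluster(Z, t=c + 1e-9, criterion="distance")
        labelings[float(c)] = labels
        k = len(np.unique(labels))
        sil = ch = db = np.nan
        if 2 <= k <= n - 1:
            sil = silhouette_score(matrix, labels, metric="precomputed")
            # CH and DB need a vector embedding; the matrix rows serve as one
            ch = calinski_harabasz_score(matrix, labels)
            db = davies_bouldin_score(matrix, labels)
        rows.append({"cutoff": float(c), "n_clusters": k, "silhouette": sil,
                     "calinski_harabasz": ch, "davies_bouldin": db})
    metrics = pd.DataFrame(rows)

    valid = metrics.dropna(subset=["silhouette"])
    if len(valid):
        best = valid.loc[valid["silhouette"].idxmax()]
        chosen = float(best["cutoff"])
    else:
        chosen = float(cutoffs[0])
    labels = labelings[chosen]
    counts = np.bincount(labels)
    dominant = int(counts.argmax())

    result = ClusterResult(matrix=matrix, linkage_method=linkage,
                           cutoffs=cutoffs, metrics=metrics, cutoff=chosen,
                           labels=labels, dominant=dominant)
    return result


def linkage_to_newick(matrix: np.ndarray, linkage: str = "average",
                      names: list[str] | None = None) -> str:
    """Dendrogram of the RMSD matrix as a Newick string (branch lengths are
    merge-height differences)."""
    condensed = squareform(np.asarray(matrix, float), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    tree = hierarchy.to_tree(Z)
    names = names or [str(i) for i in range(matrix.shape[0])]

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def representative(coords_list, member_indices, matrix: np.ndarray) -> int:
    """Member closest to the cluster-average structure.

    Members are superposed onto the cluster medoid (the member minimizing
    summed RMSD to the others), coordinates are averaged, and the member
    with the smallest superposition RMSD to that average is returned.
    Deterministic: ties resolve to the lowest index.
    """
    members = list(member_indices)
    if not members:
        raise ContractViolation("empty cluster")
    if len(members) == 1:
        return members[0]
    sub = matrix[np.ix_(members, members)]
    medoid = members[int(np.argmin(sub.sum(axis=1)))]
    target = np.asarray(coords_list[medoid], float)
    stacked = []
    for m in members:
        _, moved = kabsch_superpose(np.asarray(coords_list[m], float), target)
        stacked.append(moved)
    mean = np.mean(stacked, axis=0)
    rmsds = [kabsch_rmsd(np.asarray(coords_list[m], float), mean) for m in members]
    return members[int(np.argmin(rmsds))]
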