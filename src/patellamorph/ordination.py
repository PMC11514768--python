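"""Ordination of aligned shapes and shape-space visualisation helpers.

PCA is an eigen-decomposition of the covariance of the flattened Procrustes
residuals about the consensus.  Theoretical shapes (consensus + score x axis)
and TPS mesh warping reproduce the standard morphometric visualisation
workflow: extreme shapes along an axis, per-landmark displacement magnitudes
for colour maps, and neighbour-joining trees over specimens in the full
PC-score space.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, SurfaceMesh
from .procrustes import AlignedSample
from .tps import fit_tps, warp_points

__all__ = [
    "OrdinationResult",
    "pca",
    "theoretical_shape",
    "displacement_field",
    "warp_mesh",
    "nj_tree",
]


@dataclass
class OrdinationResult:
    consensus: np.ndarray          # (k, 3)
    eigenvectors: np.ndarray       # (n_axes, 3k), orthonormal rows
    eigenvalues: np.ndarray        # (n_axes,), descending
    variance_fractions: np.ndarray
    scores: np.ndarray             # (n, n_axes)
    specimen_ids: list[str]
    classes: np.ndarray | None = None
    curve_ids: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i + 1}" for i in range(self.n_axes)])
        df.insert(0, "specimen", self.specimen_ids)
        return df


def pca(aligned: AlignedSample) -> OrdinationResult:
    """PCA of Procrustes-aligned shapes.

    Axes are ordered by decreasing eigenvalue; the sign of each eigenvector is
    fixed so its largest-magnitude loading is positive, making scores and
    theoretical shapes reproducible across runs and BLAS builds.
    """
    n = aligned.n
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    X = aligned.flattened() - aligned.consensus.ravel()
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    # keep axes with nonzero variance (relative threshold on singular values)
    keep = s > max(1e-12 * s[0] if len(s) else 0.0, 1e-300)
    u, s, vt, eigvals = u[:, keep], s[keep], vt[keep], eigvals[keep]
    # deterministic sign convention
    for j in range(len(s)):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    total = eigvals.sum()
    c0 = aligned.sample.configurations[0]
    return OrdinationResult(
        consensus=aligned.consensus.copy(),
        eigenvectors=vt,
        eigenvalues=eigvals,
        variance_fractions=eigvals / total if total > 0 else eigvals,
        scores=scores,
        specimen_ids=aligned.specimen_ids,
        classes=c0.classes,
        curve_ids=c0.curve_ids,
    )


def theoretical_shape(ordination: OrdinationResult, axis: int, score: float) -> LandmarkConfiguration:
    """Shape at ``consensus + score * eigenvector[axis]``, e.g. an axis extreme."""
    if not 0 <= axis < ordination.n_axes:
        raise IndexError(f"axis {axis} out of range (n_axes={ordination.n_axes})")
    flat = ordination.consensus.ravel() + score * ordination.eigenvectors[axis]
    return LandmarkConfiguration(
        f"PC{axis + 1}@{score:+g}", flat.reshape(-1, 3),
        ordination.classes, ordination.curve_ids,
    )


def displacement_field(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Per-landmark Euclidean displacement between two configurations.

    Returns ``(distances, normalized)``; normalized values are in [0, 1]
    (max-scaled) and drive the colour gradient on displacement vectors.
    """
    pa = a.points if isinstance(a, LandmarkConfiguration) else np.asarray(a, dtype=float)
    pb = b.points if isinstance(b, LandmarkConfiguration) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("configurations must share one scheme")
    d = np.linalg.norm(pb - pa, axis=1)
    dmax = d.max()
    return d, d / dmax if dmax > 0 else np.zeros_like(d)


def warp_mesh(template_mesh: SurfaceMesh, template_lms, target_lms) -> SurfaceMesh:
    """Carry a template mesh through the TPS fitted on template -> target landmarks."""
    transform = fit_tps(template_lms, target_lms)
    return SurfaceMesh(warp_points(transform, template_mesh.vertices),
                       template_mesh.faces.copy())


def mesh_deformation_scalars(warped_a: SurfaceMesh, warped_b: SurfaceMesh,
                             signed: bool = True) -> np.ndarray:
    """Per-vertex deformation from mesh a to mesh b for colour maps.

    Signed values project the displacement on the vertex's (face-averaged)
    normal of ``warped_a`` — positive outward, mirroring the red/blue
    convention; ``signed=False`` returns magnitudes.
    """
    disp = warped_b.vertices - warped_a.vertices
    if not signed:
        return np.linalg.norm(disp, axis=1)
    fn = warped_a.face_normals()
    vn = np.zeros_like(warped_a.vertices)
    for f, nrm in zip(warped_a.faces, fn):
        vn[f] += nrm
    vn /= np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)
    return np.einsum("ij,ij->i", disp, vn)


# ------------------------------------------------------------ neighbour joining
def nj_tree(scores: np.ndarray, labels: list[str] | None = None,
            n_axes: int | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbour joining on Euclidean distances over PC scores.

    Uses all axes by default (``n_axes`` restricts to the first m).  Negative
    branch lengths are clamped to zero with the deficit transferred to the
    adjacent (sister) branch, preserving the path length between the joined
    leaves.  Returns an unrooted dendropy tree with leaf labels = specimen ids.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be (n, axes)")
    if n_axes is not None:
        scores = scores[:, :n_axes]
    n = len(scores)
    if n < 4:
        raise ValueError("NJ needs at least 4 specimens")
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    diff = scores[:, None, :] - scores[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    return nj_from_distance_matrix(D, labels)


def nj_from_distance_matrix(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    D = np.array(D, dtype=float)
    n = len(D)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        bi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        bj = dij - bi
        # clamp negatives, moving the deficit to the sister branch so the
        # i-j path length is preserved
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj
        # distances from the new node to the remaining ones
        new_d = np.zeros(n)
        for k_idx in active:
            if k_idx in (i, j):
                continue
            new_d[k_idx] = 0.5 * (D[i, k_idx] + D[j, k_idx] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    nodes[i].edge.length = max(D[i, j], 0.0) / 2
    root.add_child(nodes[j])
    nodes[j].edge.length = max(D[i, j], 0.0) / 2
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree
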