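"""Template projection and semilandmark sliding by bending-energy minimization.

Curve and surface semilandmarks have no point-to-point homology of their own:
their positions along a curve or across a surface are arbitrary.  The protocol
makes them geometrically homologous by (1) transferring the template's surface
points onto each specimen through a TPS fitted on the anatomical + curve
anchors, relaxing them onto the specimen mesh, and (2) iteratively sliding all
semilandmarks within their local tangent directions so as to minimise the TPS
bending energy toward a reference — first the template, then (four times by
default) the Procrustes consensus of the whole sample.

The minimisation is a single linear solve per specimen: with B the reference's
bending-energy matrix and T the matrix mapping per-landmark tangent offsets to
flattened coordinate perturbations, the offsets minimising
(y0 + T t)^T (I3 (x) B) (y0 + T t) solve
(T^T (I3 (x) B) T) t = -T^T (I3 (x) B) y0.  Curve points move along the chord
through their curve neighbours (one-sided at free endpoints); surface points
move in the tangent plane of their nearest mesh triangle.  After sliding,
curve points are re-projected onto the original curve polyline and surface
points onto the mesh, so slid points always lie on their carrier geometry.
Anatomical landmarks never move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration, ShapeSample, SurfaceMesh
from .procrustes import gpa
from .tps import bending_energy_matrix, fit_tps, warp_points

log = logging.getLogger(__name__)

__all__ = ["SlidingScheme", "project_template", "slide_once", "slide_sample"]


class TangentUndefinedError(ValueError):
    pass


@dataclass
class SlidingScheme:
    """Which landmarks slide, against what reference, and how often.

    ``reference_mode``/``n_consensus_iterations`` encode the protocol: one
    pass against the template, then ``n_consensus_iterations`` passes (default
    4) against the recomputed Procrustes consensus.  Curve endpoints are fixed
    when they coincide with an anatomical landmark, slid otherwise.
    """

    anatomical_ids: np.ndarray
    curves: list[np.ndarray]          # ordered landmark indices, one per curve
    surface_ids: np.ndarray
    reference_mode: str = "consensus"
    n_consensus_iterations: int = 4
    tangent_estimator: str = "chord"  # chord | mesh_normal (surfaces always use mesh)
    fix_curve_endpoints_on_anatomical: bool = True
    fixed_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.anatomical_ids = np.asarray(self.anatomical_ids, dtype=int)
        self.curves = [np.asarray(c, dtype=int) for c in self.curves]
        self.surface_ids = np.asarray(self.surface_ids, dtype=int)
        self.fixed_ids = np.asarray(self.fixed_ids, dtype=int)
        for c in self.curves:
            if len(c) < 3:
                raise ValueError("each curve needs at least 3 points")
        if self.n_consensus_iterations < 0:
            raise ValueError("n_consensus_iterations must be >= 0")
        ids = np.concatenate([self.anatomical_ids, *self.curves, self.surface_ids]) \
            if self.curves else np.concatenate([self.anatomical_ids, self.surface_ids])
        if len(np.unique(ids)) != len(ids):
            raise ValueError("scheme ids overlap")

    @classmethod
    def from_configuration(cls, config: LandmarkConfiguration, **kw) -> "SlidingScheme":
        anat = np.flatnonzero(config.classes == "anatomical")
        surf = np.flatnonzero(config.classes == "surface")
        curves = []
        for cid in sorted(set(config.curve_ids[config.classes == "curve"])):
            curves.append(np.flatnonzero((config.classes == "curve")
                                         & (config.curve_ids == cid)))
        return cls(anat, curves, surf, **kw)

    @property
    def k(self) -> int:
        return len(self.anatomical_ids) + sum(len(c) for c in self.curves) \
            + len(self.surface_ids)


def project_template(template: LandmarkConfiguration, template_mesh: SurfaceMesh,
                     specimen_anchors: LandmarkConfiguration,
                     specimen_mesh: SurfaceMesh) -> LandmarkConfiguration:
    """Transfer the template's surface semilandmarks onto a specimen.

    The TPS is fitted on the anchor landmarks (anatomical + curve points,
    which the specimen already carries), the template surface points are
    warped through it, then relaxed onto the specimen mesh by closest-point
    projection so every transferred point lies on the surface.
    """
    anchor_mask = template.classes != "surface"
    surf_mask = ~anchor_mask
    n_anchor = int(anchor_mask.sum())
    if specimen_anchors.k != n_anchor:
        raise ValueError(
            f"anchor-count mismatch: specimen has {specimen_anchors.k}, "
            f"template scheme expects {n_anchor}"
        )
    transform = fit_tps(template.points[anchor_mask], specimen_anchors.points)
    warped_surface = warp_points(transform, template.points[surf_mask])
    relaxed = specimen_mesh.project(warped_surface)
    points = np.empty_like(template.points)
    points[anchor_mask] = specimen_anchors.points
    points[surf_mask] = relaxed
    return LandmarkConfiguration(specimen_anchors.specimen_id, points,
                                 template.classes, template.curve_ids,
                                 specimen_anchors.side)


# ---------------------------------------------------------------- tangent frames
def _curve_tangents(points: np.ndarray, curve: np.ndarray, scale: float) -> np.ndarray:
    """Unit chord tangents through adjacent curve neighbours (one-sided at ends)."""
    P = points[curve]
    m = len(P)
    tang = np.empty((m, 3))
    for i in range(m):
        lo, hi = max(i - 1, 0), min(i + 1, m - 1)
        chord = P[hi] - P[lo]
        nrm = np.linalg.norm(chord)
        if nrm < 1e-12 * max(scale, 1e-300):
            raise TangentUndefinedError(
                f"coincident curve neighbours around landmark {curve[i]}"
            )
        tang[i] = chord / nrm
    return tang


def _surface_tangent_bases(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """(m, 3, 2) orthonormal tangent-plane bases from nearest-triangle normals."""
    normals = mesh.normals_at(points)
    bases = np.empty((len(points), 3, 2))
    for i, nrm in enumerate(normals):
        a = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        t1 = np.cross(nrm, a)
        t1 /= np.linalg.norm(t1)
        bases[i, :, 0] = t1
        bases[i, :, 1] = np.cross(nrm, t1)
    return bases


def _project_to_polyline(q: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Closest point on a polyline (chain of segments) for each query point."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    out = np.empty_like(q)
    for i, p in enumerate(q):
        ap = p[None, :] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", ab, ap) / np.maximum(denom, 1e-300), 0.0, 1.0)
        cand = a + t[:, None] * ab
        out[i] = cand[np.argmin(np.linalg.norm(cand - p, axis=1))]
    return out


# --------------------------------------------------------------------- one pass
def slide_once(config: LandmarkConfiguration, reference: LandmarkConfiguration,
               mesh: SurfaceMesh | None, scheme: SlidingScheme,
               reproject: bool = True) -> LandmarkConfiguration:
    """One sliding pass of ``config`` against ``reference``.

    Solves the restricted bending-energy minimisation over all sliding
    coordinates simultaneously, then re-projects curve points to the curve
    polyline and surface points to the mesh.  Guarantees (up to re-projection
    round-off) that the bending energy toward the reference does not increase.
    """
    if config.k != reference.k:
        raise ValueError("config and reference must share one scheme")
    k = config.k
    pts = config.points.copy()
    scale = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))

    # sliding directions: list of (landmark index, direction vector) columns
    dirs: list[tuple[int, np.ndarray]] = []
    fixed = set(scheme.fixed_ids.tolist())
    curve_slid: list[int] = []
    for curve in scheme.curves:
        tang = _curve_tangents(pts, curve, scale)
        for j, lm in enumerate(curve):
            if lm in fixed:
                continue
            endpoint = j in (0, len(curve) - 1)
            if endpoint and scheme.fix_curve_endpoints_on_anatomical and _touches_anatomical(
                    pts, lm, scheme.anatomical_ids, scale):
                continue
            dirs.append((int(lm), tang[j]))
            curve_slid.append(int(lm))
    if len(scheme.surface_ids):
        if mesh is None:
            raise ValueError("surface semilandmarks require a mesh")
        bases = _surface_tangent_bases(mesh, pts[scheme.surface_ids])
        for i, lm in enumerate(scheme.surface_ids):
            if int(lm) in fixed:
                continue
            dirs.append((int(lm), bases[i, :, 0]))
            dirs.append((int(lm), bases[i, :, 1]))
    if not dirs:
        return config.with_points(pts)

    B = bending_energy_matrix(reference.points)
    ndof = len(dirs)
    # column t of A holds B-weighted interactions; build via per-dim blocks:
    # energy(y) = sum_d y_d^T B y_d with y_d the d-th coordinate column.
    # offset t changes column d of Y by sum_c t_c e_{i_c} dir_c[d].
    idx = np.array([i for i, _ in dirs])
    V = np.array([v for _, v in dirs])          # (ndof, 3)
    # Gram matrix: G[c1,c2] = B[i1,i2] * <v1, v2>
    G = B[np.ix_(idx, idx)] * (V @ V.T)
    # rhs[c] = sum_d v_c[d] * (B @ Y[:, d])[i_c]
    BY = B @ pts                                 # (k, 3)
    rhs = np.einsum("cd,cd->c", V, BY[idx])
    # solve G t = -rhs; lstsq guards the (rare) rank-deficient tangent sets
    try:
        t = np.linalg.solve(G + 1e-12 * np.trace(G) / max(ndof, 1) * np.eye(ndof), -rhs)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(G, -rhs, rcond=None)[0]

    def apply(step: np.ndarray) -> np.ndarray:
        slid = pts.copy()
        np.add.at(slid, idx, step[:, None] * V)
        if reproject:
            movable_set = set(curve_slid)
            for curve in scheme.curves:
                movable = [lm for lm in curve if lm in movable_set]
                if movable:
                    slid[movable] = _project_to_polyline(slid[movable], pts[curve])
            if len(scheme.surface_ids):
                slid[scheme.surface_ids] = mesh.project(slid[scheme.surface_ids])
        # anatomical landmarks are immobile by construction; enforce bitwise
        slid[scheme.anatomical_ids] = config.points[scheme.anatomical_ids]
        return slid

    def energy(p: np.ndarray) -> float:
        return float(np.einsum("id,ij,jd->", p, B, p))

    # re-projection is a second-order correction but not exactly energy-neutral;
    # back off the step if it ever overshoots so a pass never increases energy
    e0 = energy(pts)
    slid = apply(t)
    for _ in range(40):
        if energy(slid) <= e0 + 1e-12 * max(abs(e0), 1.0):
            break
        t *= 0.5
        slid = apply(t)
    else:
        slid = pts.copy()
    return config.with_points(slid)


def _touches_anatomical(pts: np.ndarray, lm: int, anatomical_ids: np.ndarray,
                        scale: float) -> bool:
    if len(anatomical_ids) == 0:
        return False
    d = np.linalg.norm(pts[anatomical_ids] - pts[lm], axis=1)
    return bool(d.min() < 1e-8 * max(scale, 1e-300))


# ------------------------------------------------------------------ full sample
def slide_sample(sample: ShapeSample, template: LandmarkConfiguration,
                 meshes: dict[str, SurfaceMesh] | list[SurfaceMesh] | None,
                 scheme: SlidingScheme) -> ShapeSample:
    """Full protocol: one pass against the template, then
    ``scheme.n_consensus_iterations`` passes against the recomputed Procrustes
    consensus.  Mean bending energy per pass is logged and recorded in the
    output provenance; the result is flagged geometrically homologous.
    """
    if isinstance(meshes, list):
        meshes = dict(zip(sample.specimen_ids, meshes))
    meshes = meshes or {}

    def mesh_for(cid: str) -> SurfaceMesh | None:
        return meshes.get(cid)

    energies: list[float] = []
    configs = list(sample.configurations)

    def one_pass(reference_points: np.ndarray, tag: str) -> float:
        nonlocal configs
        ref = LandmarkConfiguration("reference", reference_points,
                                    template.classes, template.curve_ids)
        from .tps import bending_energy
        new_configs, pass_energy = [], 0.0
        for c in configs:
            slid = slide_once(c, ref, mesh_for(c.specimen_id), scheme)
            pass_energy += bending_energy(ref.points, _unit_aligned(ref.points, slid.points))
            new_configs.append(slid)
        configs = new_configs
        mean_e = pass_energy / len(configs)
        log.info("sliding pass %s: mean bending energy %.6g", tag, mean_e)
        return mean_e

    energies.append(one_pass(template.points, "template"))
    for i in range(scheme.n_consensus_iterations):
        aligned = gpa(ShapeSample(configs, sample.metadata))
        # consensus back at data scale so TPS and meshes stay commensurate
        consensus = aligned.consensus * float(np.mean(aligned.centroid_sizes))
        energies.append(one_pass(consensus, f"consensus {i + 1}"))

    prov = dict(sample.provenance)
    prov.update({
        "geometrically_homologous": True,
        "template": template.specimen_id,
        "n_passes": 1 + scheme.n_consensus_iterations,
        "mean_bending_energy_per_pass": [round(e, 10) for e in energies],
    })
    return ShapeSample(configs, sample.metadata, prov)


def _unit_aligned(ref: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Scale/translate pts to the reference's centroid and size (energy bookkeeping
    comparable across passes; rigid motion does not change bending energy)."""
    from .procrustes import centroid_size
    p = pts - pts.mean(axis=0)
    p *= centroid_size(ref) / centroid_size(p)
    return p + ref.mean(axis=0)
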