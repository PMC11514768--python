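"""Triangle-mesh container, ascii PLY / OBJ I/O, and closest-point queries.

The pipeline needs meshes for exactly two things: transferring surface
semilandmarks from the template onto each specimen (projection followed by a
relaxation step that snaps points back onto the surface) and constraining the
sliding step to each point's local tangent plane.  A minimal triangle soup with
robust closest-point queries is therefore all that is required — no repair, no
topology editing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = ["SurfaceMesh", "read_mesh", "write_mesh"]


class MeshError(ValueError):
    """Raised for empty, unreadable or structurally invalid meshes."""


@dataclass
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.size == 0:
            raise MeshError("mesh has no faces")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array of vertex indices")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinate")
        # drop zero-area faces so downstream normals are well defined
        areas = self._face_areas(self.vertices, self.faces)
        keep = areas > 1e-14 * max(self.scale, 1e-300) ** 2
        if not np.all(keep):
            log.warning("dropping %d degenerate (zero-area) faces", int((~keep).sum()))
            self.faces = self.faces[keep]
            if self.faces.size == 0:
                raise MeshError("mesh has only degenerate faces")

    # ------------------------------------------------------------------ basics
    @staticmethod
    def _face_areas(v: np.ndarray, f: np.ndarray) -> np.ndarray:
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def scale(self) -> float:
        """Bounding-box diagonal; the reference length for tolerances."""
        if len(self.vertices) == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norms, 1e-300)

    # ----------------------------------------------------- closest-point query
    def _query_structures(self):
        key = "query"
        if key not in self._cache:
            tri = self.vertices[self.faces]  # (m, 3, 3)
            centroids = tri.mean(axis=1)
            # max distance centroid -> own vertices, per face and globally
            radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
            self._cache[key] = (cKDTree(centroids), radii, float(radii.max()))
        return self._cache[key]

    def closest_points(self, query: np.ndarray):
        """Exact closest point on the mesh for each query point.

        Returns ``(points, face_indices, distances)``.  Candidate faces are
        gathered from a centroid kd-tree with a radius guaranteed to contain
        the true minimiser, then the point-triangle distance is evaluated
        exactly, so the result is exact up to floating point.
        """
        query = np.atleast_2d(np.asarray(query, dtype=float))
        tree, radii, rmax = self._query_structures()
        d1, _ = tree.query(query, k=1)
        tri = self.vertices[self.faces]
        out_p = np.empty_like(query)
        out_f = np.empty(len(query), dtype=np.intp)
        out_d = np.empty(len(query))
        for i, (q, d) in enumerate(zip(query, d1)):
            # any face containing a closer point has centroid within d + 2*rmax
            cand = tree.query_ball_point(q, d + 2.0 * rmax + 1e-12)
            cand = np.asarray(cand, dtype=np.intp)
            pts = _closest_point_on_triangles(q, tri[cand])
            dist = np.linalg.norm(pts - q, axis=1)
            j = int(np.argmin(dist))
            out_p[i], out_f[i], out_d[i] = pts[j], cand[j], dist[j]
        return out_p, out_f, out_d

    def project(self, points: np.ndarray) -> np.ndarray:
        """Snap points onto the surface (closest-point projection)."""
        return self.closest_points(points)[0]

    def normals_at(self, points: np.ndarray) -> np.ndarray:
        """Outward-ish unit normal of the nearest face for each point."""
        _, fidx, _ = self.closest_points(points)
        return self.face_normals()[fidx]

    # --------------------------------------------------------------------- I/O
    def write_ply(self, path, scalars: np.ndarray | None = None) -> None:
        """Write ascii PLY; ``scalars`` adds a per-vertex ``quality`` property."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {self.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            if scalars is not None:
                fh.write("property double quality\n")
            fh.write(f"element face {self.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for i, v in enumerate(self.vertices):
                row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
                if scalars is not None:
                    row += f" {scalars[i]:.17g}"
                fh.write(row + "\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    def write_obj(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _closest_point_on_triangles(q: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``q`` on each triangle in ``tri`` (m, 3, 3).

    Vectorised version of the textbook (Ericson) region classification.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, q[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = q[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = q[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def put(mask, pts):
        m = mask & ~done
        out[m] = pts[m] if pts.shape == out.shape else pts
        done[m] = True

    put((d1 <= 0) & (d2 <= 0), a)                                   # vertex A
    put((d3 >= 0) & (d4 <= d3), b)                                  # vertex B
    put((d6 >= 0) & (d5 <= d6), c)                                  # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / np.maximum(d1 - d3, 1e-300), 0.0)
    put((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    w_ac = d2 / np.maximum(d2 - d6, 1e-300)
    put((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    w_bc = (d4 - d3) / np.maximum((d4 - d3) + (d5 - d6), 1e-300)
    put((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b + w_bc[:, None] * (c - b))                                # edge BC
    denom = np.maximum(va + vb + vc, 1e-300)                        # interior
    v = vb / denom
    w = vc / denom
    put(np.ones(len(tri), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


# ---------------------------------------------------------------------- readers
def read_mesh(path) -> SurfaceMesh:
    """Read a PLY (ascii) or OBJ triangle mesh; quads split along the 0-2 diagonal."""
    path = str(path)
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head[:3] == b"ply":
        return _read_ply(path)
    return _read_obj(path)


def _read_ply(path: str) -> SurfaceMesh:
    with open(path, "rb") as fh:
        lines = fh.read().split(b"\n")
    fmt = None
    n_vert = n_face = 0
    vert_props: list[str] = []
    element = None
    i = 0
    for i, raw in enumerate(lines):
        tok = raw.decode("ascii", "replace").strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vert_props.append(tok[2])
        elif tok[0] == "end_header":
            break
    if fmt != "ascii":
        raise MeshError(
            f"{path}: only ascii PLY is supported (format was {fmt!r}); "
            "convert binary PLY externally"
        )
    body = [ln.decode("ascii").strip() for ln in lines[i + 1:] if ln.strip()]
    if n_vert == 0 or n_face == 0:
        raise MeshError(f"{path}: empty mesh ({n_vert} vertices, {n_face} faces)")
    ix, iy, iz = (vert_props.index(c) for c in ("x", "y", "z"))
    verts = np.empty((n_vert, 3))
    for j in range(n_vert):
        vals = body[j].split()
        verts[j] = float(vals[ix]), float(vals[iy]), float(vals[iz])
    faces = []
    for j in range(n_vert, n_vert + n_face):
        vals = [int(t) for t in body[j].split()]
        faces.extend(_triangulate(vals[1:1 + vals[0]]))
    return SurfaceMesh(verts, np.array(faces, dtype=np.intp))


def _read_obj(path: str) -> SurfaceMesh:
    verts: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for raw in fh:
            tok = raw.strip().split()
            if not tok:
                continue
            if tok[0] == "v":
                verts.append([float(t) for t in tok[1:4]])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                faces.extend(_triangulate(idx))
    if not verts or not faces:
        raise MeshError(f"{path}: empty mesh")
    return SurfaceMesh(np.array(verts), np.array(faces, dtype=np.intp))


def _triangulate(poly: list[int]) -> list[tuple[int, int, int]]:
    """Fan-triangulate a polygon; a quad splits along the 0-2 diagonal."""
    return [(poly[0], poly[i], poly[i + 1]) for i in range(1, len(poly) - 1)]


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = str(path)
    if path.endswith(".obj"):
        mesh.write_obj(path)
    else:
        mesh.write_ply(path)
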