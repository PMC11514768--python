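"""Landmark, metadata and tree containers with their on-disk formats.

Canonical landmark carrier is a long-format CSV (one row per landmark:
``specimen,landmark,class,curve,x,y,z``) because per-point class and curve
annotations do not fit the classic TPS format; TPS ``LM3=`` blocks are
supported read-only for interchange with legacy digitising tools.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .surface import SurfaceMesh, read_mesh, write_mesh  # noqa: F401  (re-export)

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "Phylogeny",
    "ShapeSample",
    "read_landmark_table",
    "write_landmark_table",
    "read_newick",
    "write_newick",
    "load_table1_fixture",
    "metadata_to_frame",
]

CLASSES = ("anatomical", "curve", "surface")


class SchemeMismatchError(ValueError):
    """Configurations in one sample must share one landmarking scheme."""


class LandmarkParseError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    """Ordered 3D landmarks of one specimen with per-point class annotations.

    ``classes`` take values in ``{anatomical, curve, surface}``; ``curve_ids``
    give the curve membership index for curve semilandmarks (-1 elsewhere).
    """

    specimen_id: str
    points: np.ndarray                      # (k, 3) float64
    classes: np.ndarray | None = None       # (k,) of str
    curve_ids: np.ndarray | None = None     # (k,) of int, -1 = not on a curve
    side: str = "unknown"                   # left | right | unknown

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be a (k, 3) array")
        k = len(self.points)
        if k < 4:
            raise ValueError(f"{self.specimen_id}: need k >= 4 landmarks, got {k}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinate")
        if self.classes is None:
            self.classes = np.full(k, "anatomical", dtype=object)
        else:
            self.classes = np.asarray(self.classes, dtype=object)
            bad = set(self.classes) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown landmark classes: {sorted(bad)}")
        if self.curve_ids is None:
            self.curve_ids = np.where(self.classes == "curve", 0, -1).astype(int)
        else:
            self.curve_ids = np.asarray(self.curve_ids, dtype=int)
        if len(self.classes) != k or len(self.curve_ids) != k:
            raise ValueError("classes/curve_ids length mismatch")
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"bad side {self.side!r}")
        # collinearity check: TPS needs a non-degenerate configuration
        centered = self.points - self.points.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < 2:
            raise ValueError(f"{self.specimen_id}: landmarks are collinear")

    @property
    def k(self) -> int:
        return len(self.points)

    def scheme_signature(self) -> tuple:
        return (self.k, tuple(self.classes), tuple(self.curve_ids))

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in CLASSES}

    def subset(self, mask: np.ndarray, specimen_id: str | None = None) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id or self.specimen_id,
            self.points[mask],
            self.classes[mask],
            self.curve_ids[mask],
            self.side,
        )

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class SpecimenMetadata:
    specimen_id: str
    species: str
    family: str                       # Rhinocerotidae | Tapiridae | Equidae
    sex: str = "U"                    # M | F | U
    age_class: str = "adult"          # adult | subadult | unknown
    body_mass: float = float("nan")   # kg, species mean
    femoral_circumference: float | None = None  # mm, optional
    taxon: str = ""                   # full (sub)species name as printed

    def __post_init__(self) -> None:
        if self.family not in ("Rhinocerotidae", "Tapiridae", "Equidae"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"sex must be M/F/U, got {self.sex!r}")
        if np.isfinite(self.body_mass) and self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not self.taxon:
            self.taxon = self.species

    @property
    def gallop(self) -> str:
        """Gallop type is a function of family: tapirs rotary, others transverse."""
        return "rotary" if self.family == "Tapiridae" else "transverse"


@dataclass
class ShapeSample:
    """Configurations sharing one landmarking scheme, with optional metadata."""

    configurations: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.configurations:
            sig = self.configurations[0].scheme_signature()
            for c in self.configurations[1:]:
                if c.scheme_signature() != sig:
                    raise SchemeMismatchError(
                        f"{c.specimen_id}: landmark scheme differs from "
                        f"{self.configurations[0].specimen_id} "
                        f"({c.k} vs {self.configurations[0].k} points)"
                    )
        if self.metadata is not None and len(self.metadata) != len(self.configurations):
            raise ValueError("metadata length mismatch")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def as_array(self) -> np.ndarray:
        """Stack into (n, k, 3)."""
        return np.stack([c.points for c in self.configurations])

    def metadata_by_id(self) -> dict[str, SpecimenMetadata]:
        if self.metadata is None:
            return {}
        return {m.specimen_id: m for m in self.metadata}

    def subsample(self, keep: np.ndarray | list[bool]) -> "ShapeSample":
        keep = np.asarray(keep, dtype=bool)
        meta = None
        if self.metadata is not None:
            meta = [m for m, k in zip(self.metadata, keep) if k]
        return ShapeSample(
            [c for c, k in zip(self.configurations, keep) if k], meta,
            dict(self.provenance),
        )


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths (time units) and unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                head = edge.head_node.taxon.label if edge.head_node.taxon else "internal node"
                raise ValueError(f"missing branch length on edge above {head!r}")
            if edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def vcv(self, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion covariance: shared root-to-MRCA path length per pair."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = list(self.tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        if order is not None:
            pos = {lab: i for i, lab in enumerate(labels)}
            missing = [t for t in order if t not in pos]
            if missing:
                raise ValueError(f"tips not in tree: {missing}")
            leaves = [leaves[pos[t]] for t in order]
            labels = list(order)
        n = len(leaves)
        pdm = self.tree.phylogenetic_distance_matrix()
        depth = np.array([lf.root_distance for lf in leaves])
        C = np.empty((n, n))
        for i in range(n):
            C[i, i] = depth[i]
            for j in range(i + 1, n):
                d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
                C[i, j] = C[j, i] = 0.5 * (depth[i] + depth[j] - d)
        return C, labels

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ------------------------------------------------------------------ landmark I/O
def read_landmark_table(path, dialect: str = "long_csv") -> list[LandmarkConfiguration]:
    """Read landmark configurations; ``dialect`` is ``long_csv`` or ``tps``.

    All configurations in one file must share the same point count (and, for
    the CSV dialect, the same class/curve scheme); a mismatch raises
    :class:`SchemeMismatchError`.
    """
    if dialect == "long_csv":
        configs = _read_long_csv(path)
    elif dialect == "tps":
        configs = _read_tps(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if configs:
        sig = configs[0].scheme_signature()
        for c in configs[1:]:
            if c.scheme_signature() != sig:
                raise SchemeMismatchError(
                    f"{path}: specimen {c.specimen_id} has {c.k} points but "
                    f"{configs[0].specimen_id} has {configs[0].k}"
                )
    return configs


def _read_long_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"specimen", "landmark", "class", "curve", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
            raise LandmarkParseError(
                f"{path}: non-numeric coordinate in column {col!r} at line {line}"
            )
    configs = []
    for spec, grp in df.groupby("specimen", sort=False):
        grp = grp.sort_values("landmark", kind="stable")
        side = str(grp["side"].iloc[0]) if "side" in grp.columns else "unknown"
        configs.append(LandmarkConfiguration(
            str(spec),
            grp[["x", "y", "z"]].to_numpy(dtype=float),
            grp["class"].to_numpy(dtype=object),
            grp["curve"].fillna(-1).to_numpy(dtype=int),
            side if side in ("left", "right") else "unknown",
        ))
    return configs


def _read_tps(path) -> list[LandmarkConfiguration]:
    """Classic TPS format, 3D blocks only (``LM3=<k>`` followed by k xyz rows)."""
    configs = []
    k_expect = 0
    pts: list[list[float]] = []
    spec_id = None
    n_anon = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if spec_id is not None:
                    configs.append(_finish_tps_block(spec_id, pts, k_expect, path))
                k_expect = int(line.split("=", 1)[1])
                pts = []
                n_anon += 1
                spec_id = f"specimen_{n_anon}"
            elif upper.startswith("LM="):
                raise LandmarkParseError(f"{path}: 2D LM= block at line {lineno}; need LM3=")
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=", "CURVES=", "POINTS=")):
                continue
            else:
                try:
                    pts.append([float(t) for t in line.split()])
                except ValueError:
                    raise LandmarkParseError(
                        f"{path}: non-numeric coordinate at line {lineno}: {line!r}"
                    ) from None
    if spec_id is not None:
        configs.append(_finish_tps_block(spec_id, pts, k_expect, path))
    return configs


def _finish_tps_block(spec_id, pts, k_expect, path) -> LandmarkConfiguration:
    if len(pts) != k_expect:
        raise LandmarkParseError(
            f"{path}: specimen {spec_id}: LM3={k_expect} but {len(pts)} rows"
        )
    arr = np.array(pts, dtype=float)
    if arr.shape[1] != 3:
        raise LandmarkParseError(f"{path}: specimen {spec_id}: rows are not x y z")
    return LandmarkConfiguration(spec_id, arr)


def write_landmark_table(configs, path, provenance: dict | None = None) -> None:
    """Write the canonical long CSV; ``provenance`` is stored as # comments."""
    if isinstance(configs, ShapeSample):
        provenance = provenance or configs.provenance
        configs = configs.configurations
    rows = []
    for c in configs:
        for i in range(c.k):
            rows.append((c.specimen_id, i, c.classes[i], int(c.curve_ids[i]),
                         c.side, c.points[i, 0], c.points[i, 1], c.points[i, 2]))
    df = pd.DataFrame(rows, columns=["specimen", "landmark", "class", "curve",
                                     "side", "x", "y", "z"])
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# ----------------------------------------------------------------------- trees
def read_newick(path_or_string) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phy.to_newick() + "\n")


# --------------------------------------------------------------------- fixtures
def _data_path(name: str):
    return importlib.resources.files("patellamorph.data").joinpath(name)


def load_table1_fixture() -> list[SpecimenMetadata]:
    """The study-design table: 54 perissodactyl patellae with taxon/sex/mass.

    27 Rhinocerotidae, 12 Tapiridae, 15 Equidae; sex encoded per row exactly as
    printed (the printed marginal totals are internally inconsistent and are
    documented, not repaired).
    """
    df = pd.read_csv(_data_path("table1_specimens.csv"), comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(SpecimenMetadata(
            specimen_id=str(r["specimen_id"]),
            species=str(r["species"]),
            family=str(r["family"]),
            sex=str(r["sex"]),
            age_class=str(r["age_class"]),
            body_mass=float(r["body_mass_kg"]),
            taxon=str(r["taxon"]),
        ))
    return out


def metadata_to_frame(meta: list[SpecimenMetadata]) -> pd.DataFrame:
    return pd.DataFrame([{
        "specimen_id": m.specimen_id, "taxon": m.taxon, "species": m.species,
        "family": m.family, "sex": m.sex, "age_class": m.age_class,
        "body_mass_kg": m.body_mass, "femoral_circumference_mm": m.femoral_circumference,
        "gallop": m.gallop,
    } for m in meta])


def load_cladogram_fixture() -> Phylogeny:
    """Composite species-level cladogram of the 16 sampled perissodactyls.

    Topology follows current consensus (Sumatran rhino sister to the genus
    *Rhinoceros*; rhinos + tapirs = Ceratomorpha sister to equids); branch
    lengths are approximate divergence depths in Myr.
    """
    return read_newick(str(_data_path("composite_cladogram.nwk")))
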