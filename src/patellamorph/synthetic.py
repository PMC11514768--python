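"""Synthetic patella-like samples with known, recoverable structure.

The generator emulates the statistical structure the downstream analysis
assumes rather than real anatomy: a stylized kneecap (a rounded-triangular
deformed ellipsoid with an optional medial protrusion) carries the standard
landmarking scheme (6 anatomical, 103 curve, 461 surface points by default);
species mean shapes diverge by Brownian motion on a supplied phylogeny inside
a smooth 20-mode shape basis; specimens add an allometric component along a
fixed direction (calibrated so the expected shape-on-size regression R^2
equals ``allometry_fraction`` when size and noise are the only within-species
effects), an optional sex offset, and isotropic digitization noise; a
clade-linked medial-angle parameter reproduces the rhino/equid vs tapir
asymmetry contrast.  Every random draw derives from the design seed, so
generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import (
    LandmarkConfiguration,
    Phylogeny,
    ShapeSample,
    SpecimenMetadata,
    SurfaceMesh,
    load_cladogram_fixture,
)
from .phylo import bm_simulate
from .procrustes import centroid_size
from .tps import fit_tps, warp_points

__all__ = [
    "TemplateBundle",
    "SyntheticDesign",
    "SyntheticSample",
    "make_template",
    "simulate_sample",
    "repeatability_protocol",
    "composite_cladogram_fixture",
    "family_of_species",
]

#: structural seed for the shape-mode basis: part of the stated world, not a dial
_MODE_SEED = 20240318


def family_of_species(species: str) -> str:
    genus = species.split()[0].split("_")[0].casefold()
    if genus == "equus":
        return "Equidae"
    if genus == "tapirus":
        return "Tapiridae"
    return "Rhinocerotidae"


# ------------------------------------------------------------------ icosphere
def _icosphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.intp)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.intp)
    return verts, faces


# --------------------------------------------------------------- parametric bone
def _patella_surface(directions: np.ndarray, medial_angle: float) -> np.ndarray:
    """Map unit-sphere directions to the stylized patellar shell.

    x: proximodistal (apex at -x), y: mediolateral (medial at +y),
    z: craniocaudal (articular surface at -z).  ``medial_angle`` in [0, 1]
    grows a medial protrusion; 0 gives a bone mirror-symmetric in y.
    """
    u = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    a, b, c = 1.15, 0.90, 0.62
    p = u * np.array([a, b, c])
    # rounded-triangular taper: narrower toward the distal apex
    taper = 1.0 - 0.28 / (1.0 + np.exp(4.0 * p[:, 0] / a))
    p[:, 1] *= taper
    p[:, 2] *= taper
    # medial protrusion (the "medial angle"), smoothly gated to the medial side
    gate = 0.5 * (1.0 + np.tanh(p[:, 1] / 0.18))
    bump = np.exp(-((p[:, 0] - 0.05) ** 2 / 0.35 + p[:, 2] ** 2 / 0.22))
    p[:, 1] += medial_angle * 0.55 * gate * bump
    return p


def _slerp(u: np.ndarray, v: np.ndarray, w: float) -> np.ndarray:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    dot = float(np.clip(u @ v, -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        return u
    return (np.sin((1 - w) * omega) * u + np.sin(w * omega) * v) / np.sin(omega)


def _fibonacci_half_sphere(n_pairs: int, n_plane: int) -> np.ndarray:
    """Quasi-uniform directions: n_pairs mirror pairs (y>0 then their y<0
    images, interleaved pair-wise) plus n_plane points on the y=0 meridian."""
    golden = (1 + 5 ** 0.5) / 2
    dirs = []
    i = 0
    made = 0
    while made < n_pairs:
        zc = 1 - 2 * ((i + 0.5) / (2 * n_pairs + 1))
        theta = 2 * np.pi * i / golden
        r = np.sqrt(max(1 - zc * zc, 0.0))
        d = np.array([r * np.cos(theta), abs(r * np.sin(theta)), zc])
        i += 1
        if d[1] < 0.05:        # too close to the plane to make a clean pair
            continue
        dirs.append(d)
        dirs.append(d * np.array([1.0, -1.0, 1.0]))
        made += 1
    for j in range(n_plane):
        ang = 2 * np.pi * (j + 0.37) / n_plane
        dirs.append(np.array([np.cos(ang), 0.0, np.sin(ang)]))
    return np.array(dirs)


@dataclass
class TemplateBundle:
    """Template configuration + mesh + structural extras.

    Iterable as ``(config, mesh)`` to match the documented return pair;
    ``mirror_permutation`` maps each landmark to its sagittal-mirror partner
    (identity on plane landmarks), and ``modes`` is the orthonormal smooth
    shape basis (row 0 the allometry direction, rows 1..n_modes the
    evolutionary modes, last row the dimorphism direction).
    """

    config: LandmarkConfiguration
    mesh: SurfaceMesh
    medial_angle: float
    mirror_permutation: np.ndarray
    modes: np.ndarray                 # (n_modes + 2, 3k)

    def __iter__(self):
        return iter((self.config, self.mesh))


def make_template(n_curve: int = 103, n_surface: int = 461,
                  medial_angle: float = 0.6, n_modes: int = 20,
                  mesh_subdivisions: int = 3) -> TemplateBundle:
    """Build the stylized patella template with the standard landmark scheme.

    Landmarks are snapped onto the generated mesh, so every point lies on the
    surface to round-off.  At ``medial_angle=0`` the landmark set is
    mirror-symmetric under ``mirror_permutation``.
    """
    if n_curve < 6 or n_surface < 1:
        raise ValueError("scheme too small")
    sphere_v, faces = _icosphere(mesh_subdivisions)
    vertices = _patella_surface(sphere_v, medial_angle)
    mesh = SurfaceMesh(vertices, faces)

    # --- anatomical landmarks: sagittal-plane directions drifting medially
    # with medial_angle (so the medial_angle=0 bone has a symmetric scheme)
    plane_dirs = np.array([
        [0.95, 0.0, 0.40],    # 1 most proximal point of the medial ridge
        [-0.98, 0.0, 0.25],   # 2 most distal point of the medial ridge
        [-0.10, 0.0, -0.99],  # 3 most medial point of the medial articular surface
        [0.60, 0.0, -0.80],   # 4 most proximal point of the medial articular surface
        [0.99, 0.0, -0.15],   # 5 most proximal point of the base
        [0.05, 0.0, 0.99],    # 6 most medial point of the medial angle
    ])
    medial_dirs = np.array([
        [0.90, 0.30, 0.35],
        [-0.95, 0.25, 0.20],
        [-0.10, 0.60, -0.79],
        [0.55, 0.45, -0.70],
        [0.95, 0.30, -0.12],
        [0.05, 0.90, 0.40],
    ])
    anat_dirs = np.array([_slerp(p, m, medial_angle)
                          for p, m in zip(plane_dirs, medial_dirs)])

    # --- curve 1: "medial ridge" meridian (in the symmetric plane at angle 0)
    n_c1 = n_curve // 2 + n_curve % 2
    n_c2 = n_curve - n_c1
    s = np.linspace(0.0, 1.0, n_c1)
    theta = np.pi * (0.15 + 0.7 * s)            # proximal -> distal over the cranial face
    ridge_plane = np.column_stack([np.cos(theta), np.zeros(n_c1), np.sin(theta)])
    ridge_medial = np.column_stack([np.cos(theta),
                                    0.45 * np.sin(np.pi * s), np.sin(theta)])
    c1_dirs = np.array([_slerp(p, m, medial_angle)
                        for p, m in zip(ridge_plane, ridge_medial)])
    # --- curve 2: articular-margin loop around the caudal face (y-symmetric)
    t = np.linspace(0.0, 2 * np.pi, n_c2, endpoint=False)
    phi = np.deg2rad(55.0)
    c2_dirs = np.column_stack([np.sin(phi) * np.cos(t), np.sin(phi) * np.sin(t),
                               -np.cos(phi) * np.ones(n_c2)])

    # --- surface semilandmarks: mirror-paired quasi-uniform directions
    n_pairs = n_surface // 2
    n_plane = n_surface - 2 * n_pairs
    surf_dirs = _fibonacci_half_sphere(n_pairs, n_plane)

    dirs = np.vstack([anat_dirs, c1_dirs, c2_dirs, surf_dirs])
    points = mesh.project(_patella_surface(dirs, medial_angle))

    k = len(points)
    classes = np.array(["anatomical"] * 6 + ["curve"] * n_curve
                       + ["surface"] * n_surface, dtype=object)
    curve_ids = np.array([-1] * 6 + [0] * n_c1 + [1] * n_c2 + [-1] * n_surface)
    config = LandmarkConfiguration("template", points, classes, curve_ids, side="right")

    # mirror permutation: anatomical + ridge are plane landmarks (identity at
    # angle 0); the loop reverses; surface pairs swap; plane extras identity
    perm = np.arange(k)
    loop0 = 6 + n_c1
    for j in range(n_c2):
        perm[loop0 + j] = loop0 + ((n_c2 - j) % n_c2)
    surf0 = 6 + n_curve
    for j in range(n_pairs):
        perm[surf0 + 2 * j] = surf0 + 2 * j + 1
        perm[surf0 + 2 * j + 1] = surf0 + 2 * j

    modes = _shape_modes(points, n_modes)
    return TemplateBundle(config, mesh, medial_angle, perm, modes)


def _similarity_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis (7, 3k) of similarity directions at a configuration:
    3 translations, 3 infinitesimal rotations, 1 scaling."""
    k = len(points)
    c = points - points.mean(axis=0)
    fields = []
    for d in range(3):
        f = np.zeros((k, 3))
        f[:, d] = 1.0
        fields.append(f.ravel())
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)]
    for g in gens:
        fields.append((c @ g.T).ravel())
    fields.append(c.ravel())
    basis, _ = np.linalg.qr(np.array(fields).T)
    return basis.T


def _shape_modes(points: np.ndarray, n_modes: int) -> np.ndarray:
    """Smooth orthonormal displacement fields orthogonal to similarity motions.

    Row 0 is reserved as the allometric direction, rows 1..n_modes carry the
    Brownian shape divergence, and the final row is the sexual-dimorphism
    direction.  Gaussian-bump fields with a fixed structural seed keep species
    differences spatially coherent (not white noise).
    """
    rng = np.random.default_rng(_MODE_SEED)
    k = len(points)
    sim = _similarity_basis(points)
    raw = []
    for _ in range(n_modes + 2):
        center = points[rng.integers(k)]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        width = 0.55
        w = np.exp(-np.sum((points - center) ** 2, axis=1) / (2 * width ** 2))
        raw.append((w[:, None] * direction).ravel())
    M = np.array(raw)
    M -= (M @ sim.T) @ sim            # project out similarity motions
    q, r = np.linalg.qr(M.T)
    # fix signs for reproducibility across BLAS builds
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


# ------------------------------------------------------------------- the design
@dataclass
class SyntheticDesign:
    """Stated world for a simulated sample; defaults mirror the study design.

    ``bm_rate`` is shape variance per Myr per mode; ``allometry_fraction`` the
    target share of within-species shape variance explained by log size;
    ``noise_sd`` the per-coordinate digitization noise (template units, the
    template having centroid size ~= 17); ``asymmetry_by_clade`` maps family
    to the medial-angle parameter (tapirs symmetric, rhinos/equids not).
    """

    tree: Phylogeny | None = None
    n_per_species: int | dict[str, int] = 3
    bm_rate: float = 1e-3
    allometry_fraction: float = 0.12
    noise_sd: float = 2e-3
    dimorphism_effect: float = 0.0
    asymmetry_by_clade: dict[str, float] = field(default_factory=lambda: {
        "Rhinocerotidae": 0.72, "Equidae": 0.60, "Tapiridae": 0.35})
    body_mass: dict[str, float] | None = None
    size_log_sd: float = 0.12
    n_curve: int = 103
    n_surface: int = 461
    n_modes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allometry_fraction < 1.0:
            raise ValueError("allometry_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tree is None:
            self.tree = load_cladogram_fixture()
        n = self.n_per_species
        if isinstance(n, int) and n < 1 or isinstance(n, dict) and min(n.values()) < 1:
            raise ValueError("n_per_species must be >= 1")

    def counts(self) -> dict[str, int]:
        tips = self.tree.tip_labels
        if isinstance(self.n_per_species, dict):
            return {t: int(self.n_per_species[t]) for t in tips}
        return {t: int(self.n_per_species) for t in tips}

    def masses(self) -> dict[str, float]:
        if self.body_mass is not None:
            return dict(self.body_mass)
        return {t: _DEFAULT_MASSES.get(t, 500.0) for t in self.tree.tip_labels}


#: species-mean body masses (kg) of the sampled taxa
_DEFAULT_MASSES = {
    "Ceratotherium_simum": 2300, "Diceros_bicornis": 1050,
    "Dicerorhinus_sumatrensis": 775, "Rhinoceros_sondaicus": 1350,
    "Rhinoceros_unicornis": 2000, "Tapirus_bairdii": 260, "Tapirus_indicus": 340,
    "Tapirus_pinchaque": 175, "Tapirus_terrestris": 220, "Equus_africanus": 275,
    "Equus_hemionus": 230, "Equus_ferus": 370, "Equus_burchellii": 247,
    "Equus_grevyi": 400, "Equus_quagga": 247, "Equus_zebra": 310,
}


@dataclass
class SyntheticSample:
    sample: ShapeSample                      # raw configurations + metadata
    template: TemplateBundle
    design: SyntheticDesign
    meshes: dict[str, SurfaceMesh]
    ground_truth: dict

    def __iter__(self):
        return iter((self.sample, self.meshes))


def simulate_sample(design: SyntheticDesign,
                    generate_meshes: bool = False) -> SyntheticSample:
    """Draw a full synthetic sample from the design.

    Species mean shapes = clade-specific template (medial angle) + Brownian
    divergence in the smooth mode basis; specimens add the calibrated
    allometric displacement, an optional sex offset, isotropic noise, a random
    rigid motion and their individual scale.  Per-specimen meshes (TPS warps
    of the template mesh) are produced only on request — they are needed by
    the projection/sliding stages, not by the statistics.
    """
    rng = np.random.default_rng(design.seed)
    bundle = make_template(design.n_curve, design.n_surface,
                           medial_angle=0.6, n_modes=design.n_modes)
    template = bundle.config
    k = template.k
    cs_template = centroid_size(template)

    tips = design.tree.tip_labels
    counts = design.counts()
    masses = design.masses()

    # species mean shapes: clade template + BM in the mode basis
    bm_scores, bm_labels = bm_simulate(design.tree, design.bm_rate,
                                       dims=design.n_modes,
                                       seed=int(rng.integers(2 ** 31)))
    bm_by_species = dict(zip(bm_labels, bm_scores))
    dirs_template = template.points
    species_mean: dict[str, np.ndarray] = {}
    for sp in tips:
        fam = family_of_species(sp)
        angle = design.asymmetry_by_clade.get(fam, bundle.medial_angle)
        base = _retarget_medial_angle(bundle, angle)
        disp = bm_by_species[sp] @ bundle.modes[1:1 + design.n_modes]
        species_mean[sp] = base + disp.reshape(k, 3)

    # allometry slope calibrated against the within-species noise budget
    allo_vec = bundle.modes[0]
    mass_arr = np.array([masses[sp] for sp in tips for _ in range(counts[sp])])
    log_cs_mean = np.log(cs_template) + (np.log(mass_arr) - np.log(np.median(mass_arr))) / 3.0
    var_logs = np.var(log_cs_mean) + design.size_log_sd ** 2
    noise_var_total = 3 * k * design.noise_sd ** 2
    rho = design.allometry_fraction
    beta = np.sqrt(rho / (1 - rho) * noise_var_total / var_logs) if rho > 0 else 0.0

    sex_vec = bundle.modes[-1]
    configs, meta, meshes = [], [], {}
    truth_logsize, truth_sex = [], []
    i_specimen = 0
    for sp in tips:
        fam = family_of_species(sp)
        for j in range(counts[sp]):
            mu_log = np.log(cs_template) + (np.log(masses[sp]) - np.log(np.median(mass_arr))) / 3.0
            log_s = mu_log + design.size_log_sd * rng.standard_normal()
            sex = "M" if rng.random() < 0.5 else "F"
            flat = species_mean[sp].ravel().copy()
            flat = flat + beta * (log_s - np.mean(log_cs_mean)) * allo_vec
            if design.dimorphism_effect:
                flat = flat + (0.5 if sex == "M" else -0.5) * design.dimorphism_effect * sex_vec
            shape = flat.reshape(k, 3) + design.noise_sd * rng.standard_normal((k, 3))
            # place at its own size, position and orientation
            shape = shape - shape.mean(axis=0)
            shape = shape * (np.exp(log_s) / centroid_size(shape))
            shape = shape @ _random_rotation(rng) + rng.uniform(-10, 10, size=3)
            sid = f"{sp}_{j + 1:02d}"
            config = LandmarkConfiguration(sid, shape, template.classes,
                                           template.curve_ids, side="right")
            configs.append(config)
            fc = 40.0 * (masses[sp] / 100.0) ** (1.0 / 3.0) * np.exp(0.05 * rng.standard_normal())
            meta.append(SpecimenMetadata(
                specimen_id=sid, species=sp.replace("_", " "), family=fam, sex=sex,
                body_mass=float(masses[sp]), femoral_circumference=float(fc),
                taxon=sp.replace("_", " ")))
            if generate_meshes:
                transform = fit_tps(template.points, config.points)
                meshes[sid] = SurfaceMesh(
                    warp_points(transform, bundle.mesh.vertices),
                    bundle.mesh.faces.copy())
            truth_logsize.append(log_s)
            truth_sex.append(sex)
            i_specimen += 1

    sample = ShapeSample(configs, meta, provenance={"design_seed": design.seed})
    truth = {
        "species_mean_shapes": species_mean,
        "allometry_vector": allo_vec,
        "beta": beta,
        "log_sizes": np.array(truth_logsize),
        "bm_scores": bm_by_species,
    }
    return SyntheticSample(sample, bundle, design, meshes, truth)


_RETARGET_CACHE: dict[tuple, np.ndarray] = {}


def _retarget_medial_angle(bundle: TemplateBundle, angle: float) -> np.ndarray:
    """Template landmark positions re-generated at a different medial angle."""
    if abs(angle - bundle.medial_angle) < 1e-12:
        return bundle.config.points.copy()
    n_curve = int(np.sum(bundle.config.classes == "curve"))
    n_surface = int(np.sum(bundle.config.classes == "surface"))
    key = (n_curve, n_surface, round(angle, 12))
    if key not in _RETARGET_CACHE:
        sub = make_template(n_curve=n_curve, n_surface=n_surface,
                            medial_angle=angle, n_modes=2)
        _RETARGET_CACHE[key] = sub.config.points
    return _RETARGET_CACHE[key].copy()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ------------------------------------------------------- repeatability protocol
def repeatability_protocol(config: LandmarkConfiguration, n_specimens: int = 3,
                           n_digitizations: int = 10, digitization_sd: float = 0.01,
                           seed: int | None = None,
                           specimen_separation: float | None = None) -> ShapeSample:
    """Emulate the landmarking repeatability test: a few close-shaped specimens,
    each digitized repeatedly with independent jitter on the anatomical
    landmarks.

    ``specimen_separation`` is the per-coordinate SD of the between-specimen
    shape offsets (default 10 x ``digitization_sd``); with jitter below the
    separation, within-specimen dispersion stays below between-specimen
    dispersion in the GPA+PCA morphospace.
    """
    if digitization_sd <= 0:
        raise ValueError("digitization_sd must be > 0")
    rng = np.random.default_rng(seed)
    anat = config.subset(config.classes == "anatomical") \
        if np.any(config.classes != "anatomical") else config
    if specimen_separation is None:
        specimen_separation = 10.0 * digitization_sd
    configs = []
    for s in range(n_specimens):
        base = anat.points + specimen_separation * rng.standard_normal(anat.points.shape)
        for r in range(n_digitizations):
            pts = base + digitization_sd * rng.standard_normal(base.shape)
            configs.append(LandmarkConfiguration(
                f"specimen{s + 1}_rep{r + 1:02d}", pts,
                anat.classes, anat.curve_ids))
    return ShapeSample(configs, provenance={
        "protocol": "repeatability", "n_specimens": n_specimens,
        "n_digitizations": n_digitizations, "digitization_sd": digitization_sd,
        "specimen_separation": specimen_separation, "seed": seed,
    })


def composite_cladogram_fixture() -> Phylogeny:
    """The 16-taxon species-level cladogram (5 rhinos, 4 tapirs, 7 equids)."""
    return load_cladogram_fixture()
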