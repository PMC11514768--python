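"""End-to-end orchestration of the three analyses on one sample.

``run_pipeline`` executes the published protocol on a (real or synthetic)
sample: mirror left bones, project the template's surface semilandmarks,
slide (one template pass + consensus passes), GPA, PCA, NJ tree, Pearson
tests of PC1/PC2 vs log CS, PERMANOVAs (species + sex; gallop for the
all-perissodactyl run), Procrustes ANOVAs of shape on log CS (and log FC when
present), species mean shapes, and — for the full-sample run only — Blomberg
K on mean CS and Kmult on species-mean PC scores.  Every statistic lands in a
machine-readable report whose entries all trace to artifacts on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .landmark_io import (
    Phylogeny,
    ShapeSample,
    metadata_to_frame,
    write_landmark_table,
    write_newick,
)
from .ordination import (
    displacement_field,
    mesh_deformation_scalars,
    nj_tree,
    pca,
    theoretical_shape,
    warp_mesh,
)
from .phylo import blomberg_k, k_mult
from .procrustes import gpa, mirror, species_mean_shapes
from .sliding import SlidingScheme, project_template, slide_sample
from .stats import allometric_shapes, pearson_test, permanova, procrustes_anova
from .synthetic import SyntheticDesign, SyntheticSample, simulate_sample

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """What to run, on what, with which seeds; serialized next to the outputs."""

    out_dir: str | Path = "pipeline_out"
    design: SyntheticDesign | None = None          # synthetic input ...
    sample: ShapeSample | None = None              # ... or an explicit sample
    meshes: dict | None = None
    template_id: str | None = None                 # specimen used as template
    tree: Phylogeny | None = None
    family_filter: str | None = None               # e.g. "Rhinocerotidae"
    do_sliding: bool = True
    n_consensus_iterations: int = 4
    n_permutations_permanova: int = 999
    n_permutations_procrustes: int = 1000
    n_permutations_signal: int = 1000
    phylogenetic_signal: bool = True               # full-sample runs only
    seed: int = 1
    write_meshes: bool = True
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("design", "sample", "meshes", "tree")}
        d["out_dir"] = str(self.out_dir)
        d["synthetic"] = self.design is not None
        if self.design is not None:
            d["design"] = {
                "seed": self.design.seed, "bm_rate": self.design.bm_rate,
                "allometry_fraction": self.design.allometry_fraction,
                "noise_sd": self.design.noise_sd,
                "n_per_species": self.design.n_per_species
                if isinstance(self.design.n_per_species, int)
                else dict(self.design.n_per_species),
            }
        return json.dumps(d, indent=2, default=str)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"artifacts": {}, "seed": config.seed}

    def artifact(name: str, path: Path):
        report["artifacts"][name] = str(path)

    # ---------------------------------------------------------------- inputs
    stage = "input"
    try:
        if config.sample is not None:
            sample, meshes = config.sample, dict(config.meshes or {})
            template_bundle = None
        else:
            design = config.design or SyntheticDesign(seed=config.seed)
            synth: SyntheticSample = simulate_sample(
                design, generate_meshes=config.do_sliding)
            sample, meshes = synth.sample, synth.meshes
            template_bundle = synth.template
        tree = config.tree
        if tree is None and config.design is not None:
            tree = config.design.tree
        if tree is None and config.sample is None:
            tree = (config.design or SyntheticDesign(seed=config.seed)).tree
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    meta = {m.specimen_id: m for m in (sample.metadata or [])}
    if config.family_filter:
        keep = [meta[c.specimen_id].family == config.family_filter
                for c in sample.configurations]
        sample = sample.subsample(keep)
        meshes = {sid: meshes[sid] for sid in sample.specimen_ids if sid in meshes}
    report["n_specimens"] = len(sample)

    # ---------------------------------------------------------------- mirror
    stage = "mirror"
    configs = [mirror(c) if c.side == "left" else c for c in sample.configurations]
    sample = ShapeSample(configs, sample.metadata if not config.family_filter
                         else sample.metadata, sample.provenance)

    # ----------------------------------------------- template, project, slide
    if config.do_sliding:
        stage = "project+slide"
        try:
            template_cfg = _pick_template(sample, config.template_id, template_bundle)
            scheme = SlidingScheme.from_configuration(
                template_cfg, n_consensus_iterations=config.n_consensus_iterations)
            projected = []
            for c in sample.configurations:
                mesh = meshes.get(c.specimen_id)
                if mesh is not None and np.any(template_cfg.classes == "surface"):
                    anchors = c.subset(c.classes != "surface")
                    projected.append(project_template(template_cfg,
                                                      meshes.get(template_cfg.specimen_id,
                                                                 mesh),
                                                      anchors, mesh))
                else:
                    projected.append(c)
            sample = ShapeSample(projected, sample.metadata, sample.provenance)
            sample = slide_sample(sample, template_cfg, meshes, scheme)
            report["sliding"] = {
                "template": template_cfg.specimen_id,
                "mean_bending_energy_per_pass":
                    sample.provenance.get("mean_bending_energy_per_pass"),
            }
            p = out / "slid_landmarks.csv"
            write_landmark_table(sample, p)
            artifact("slid_landmarks", p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------------- GPA
    stage = "gpa"
    try:
        aligned = gpa(sample)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    p = out / "centroid_sizes.csv"
    aligned.sizes_frame().to_csv(p, index=False)
    artifact("centroid_sizes", p)
    p = out / "aligned_landmarks.csv"
    write_landmark_table(aligned.aligned_configurations(), p)
    artifact("aligned_landmarks", p)

    # ------------------------------------------------------------------- PCA
    stage = "pca"
    ordination = pca(aligned)
    report["pca"] = {
        "variance_fractions": ordination.variance_fractions[:10].round(6).tolist(),
        "pc1_fraction": float(ordination.variance_fractions[0]),
        "pc2_fraction": float(ordination.variance_fractions[1]),
    }
    p = out / "pc_scores.csv"
    df = ordination.scores_frame()
    if sample.metadata:
        df = df.merge(metadata_to_frame(sample.metadata), left_on="specimen",
                      right_on="specimen_id", how="left").drop(columns=["specimen_id"])
    df.to_csv(p, index=False)
    artifact("pc_scores", p)

    # -------------------------------------------------------------------- NJ
    stage = "nj"
    if aligned.n >= 4:
        tree_nj = nj_tree(ordination.scores, ordination.specimen_ids)
        p = out / "nj_tree.nwk"
        with open(p, "w") as fh:
            fh.write(tree_nj.as_string(schema="newick", suppress_rooting=True))
        artifact("nj_tree", p)

    # ------------------------------------------------------- Pearson (PC vs CS)
    stage = "pearson"
    log_cs = np.log(aligned.centroid_sizes)
    report["pearson"] = {}
    for axis in (0, 1):
        res = pearson_test(log_cs, ordination.scores[:, axis])
        report["pearson"][f"PC{axis + 1}_vs_logCS"] = {
            "r": round(res.r, 4), "t": round(res.t, 4), "dF": res.df,
            "P": round(res.p, 6), "flag": res.flag,
        }

    # --------------------------------------------------------------- PERMANOVA
    stage = "permanova"
    report["permanova"] = {}
    if sample.metadata:
        mlist = sample.metadata
        species = [m.species for m in mlist]
        sex = [m.sex if m.sex in ("M", "F") else None for m in mlist]
        rng = np.random.default_rng(config.seed)
        if len(set(species)) > 1 and len(set(s for s in sex if s)) > 1:
            tab = permanova(ordination.scores, [species, sex],
                            n_permutations=config.n_permutations_permanova,
                            seed=int(rng.integers(2 ** 31)),
                            factor_names=["species", "sex"])
            p = out / "permanova_species_sex.csv"
            tab.to_csv(p)
            artifact("permanova_species_sex", p)
            report["permanova"]["species_sex"] = _anova_summary(tab)
        gallop = [m.gallop for m in mlist]
        if len(set(gallop)) > 1:
            tab = permanova(ordination.scores, [gallop],
                            n_permutations=config.n_permutations_permanova,
                            seed=int(rng.integers(2 ** 31)), factor_names=["gallop"])
            p = out / "permanova_gallop.csv"
            tab.to_csv(p)
            artifact("permanova_gallop", p)
            report["permanova"]["gallop"] = _anova_summary(tab)

    # -------------------------------------------------------- Procrustes ANOVA
    stage = "procrustes_anova"
    rng = np.random.default_rng(config.seed + 1)
    report["procrustes_anova"] = {}
    tab_cs = procrustes_anova(aligned, log_cs,
                              n_permutations=config.n_permutations_procrustes,
                              seed=int(rng.integers(2 ** 31)), term="log CS")
    p = out / "procrustes_anova_logCS.csv"
    tab_cs.to_csv(p)
    artifact("procrustes_anova_logCS", p)
    report["procrustes_anova"]["log_CS"] = _anova_summary(tab_cs)
    if sample.metadata and any(m.femoral_circumference for m in sample.metadata):
        fc = [np.log(m.femoral_circumference) if m.femoral_circumference else None
              for m in sample.metadata]
        tab_fc = procrustes_anova(aligned, fc,
                                  n_permutations=config.n_permutations_procrustes,
                                  seed=int(rng.integers(2 ** 31)), term="log FC")
        p = out / "procrustes_anova_logFC.csv"
        tab_fc.to_csv(p)
        artifact("procrustes_anova_logFC", p)
        report["procrustes_anova"]["log_FC"] = _anova_summary(tab_fc)
        fc_vals = np.array([m.femoral_circumference or np.nan for m in sample.metadata])
        keepfc = np.isfinite(fc_vals)
        if keepfc.sum() >= 3:
            res = pearson_test(log_cs[keepfc], np.log(fc_vals[keepfc]))
            report["pearson"]["logCS_vs_logFC"] = {
                "r": round(res.r, 4), "t": round(res.t, 4), "dF": res.df,
                "P": round(res.p, 6), "flag": res.flag}

    # -------------------------------- theoretical shapes and deformation maps
    stage = "shapes"
    shape_pairs = {}
    for axis in (0, 1):
        lo = theoretical_shape(ordination, axis, float(ordination.scores[:, axis].min()))
        hi = theoretical_shape(ordination, axis, float(ordination.scores[:, axis].max()))
        shape_pairs[f"PC{axis + 1}"] = (lo, hi)
    shape_pairs["allometry"] = allometric_shapes(tab_cs)
    report["deformation"] = {}
    for name, (lo, hi) in shape_pairs.items():
        d, _ = displacement_field(lo, hi)
        report["deformation"][name] = {"max_displacement": float(d.max()),
                                       "mean_displacement": float(d.mean())}
        if config.write_meshes and template_bundle is not None:
            mesh_lo = warp_mesh(template_bundle.mesh, template_bundle.config.points,
                                _rescale(lo.points, template_bundle))
            mesh_hi = warp_mesh(template_bundle.mesh, template_bundle.config.points,
                                _rescale(hi.points, template_bundle))
            scal = mesh_deformation_scalars(mesh_lo, mesh_hi)
            pth = out / f"shape_{name}_max.ply"
            mesh_hi.write_ply(pth, scalars=scal)
            artifact(f"shape_{name}_max", pth)

    # --------------------------------------------- species means + phylo signal
    stage = "phylogenetic_signal"
    if (config.phylogenetic_signal and not config.family_filter
            and sample.metadata and tree is not None):
        try:
            species = [m.species for m in sample.metadata]
            means = species_mean_shapes(aligned, species)
            aligned2 = gpa(means)
            ord2 = pca(aligned2)
            labels = [c.specimen_id for c in means.configurations]
            cs_by_species: dict[str, list[float]] = {}
            for m, cs in zip(sample.metadata, aligned.centroid_sizes):
                cs_by_species.setdefault(m.species, []).append(cs)
            mean_cs = {sp: float(np.mean(v)) for sp, v in cs_by_species.items()}
            rng = np.random.default_rng(config.seed + 2)
            k_res = blomberg_k(tree, mean_cs,
                               n_permutations=config.n_permutations_signal,
                               seed=int(rng.integers(2 ** 31)))
            km_res = k_mult(tree, ord2.scores, labels,
                            n_permutations=config.n_permutations_signal,
                            seed=int(rng.integers(2 ** 31)))
            report["phylogenetic_signal"] = {
                "K_meanCS": {"K": round(k_res.statistic, 4), "P": round(k_res.p, 6)},
                "Kmult_shape": {"Kmult": round(km_res.statistic, 4),
                                "P": round(km_res.p, 6)},
            }
            p = out / "species_mean_shapes.csv"
            write_landmark_table(means, p)
            artifact("species_mean_shapes", p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---------------------------------------------------------------- report
    p = out / "run_config.json"
    p.write_text(config.to_json())
    artifact("run_config", p)
    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2, default=str))
    return report


def _anova_summary(tab) -> dict:
    rows = {}
    for r in tab.rows:
        rows[r.term] = {"Df": r.df, "SS": round(r.ss, 6),
                        "R2": round(r.r2, 4) if r.r2 is not None else None,
                        "F": round(r.f, 4) if r.f is not None else None,
                        "Z": round(r.z, 4) if r.z is not None else None,
                        "P": round(r.p, 6) if r.p is not None else None}
    rows["n_excluded"] = tab.n_excluded
    return rows


def _pick_template(sample: ShapeSample, template_id: str | None, bundle):
    if template_id is not None:
        for c in sample.configurations:
            if c.specimen_id == template_id:
                return c
        raise ValueError(f"template specimen {template_id!r} not in sample")
    if bundle is not None:
        return bundle.config
    # default mirrors the published choice: the most average-shaped specimen
    from .procrustes import procrustes_distance
    arr = sample.as_array()
    mean = arr.mean(axis=0)
    dists = [procrustes_distance(c.points, mean) for c in sample.configurations]
    return sample.configurations[int(np.argmin(dists))]


def _rescale(points: np.ndarray, bundle) -> np.ndarray:
    """Bring unit-size aligned shapes back to template scale for mesh warps."""
    from .procrustes import centroid_size
    pts = np.asarray(points, dtype=float)
    return pts * (centroid_size(bundle.config.points) / centroid_size(pts))
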