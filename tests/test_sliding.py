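"""Template projection and bending-energy sliding, incl. a grid-search oracle."""

import numpy as np
import pytest

from patellamorph.landmark_io import LandmarkConfiguration, ShapeSample
from patellamorph.sliding import (
    SlidingScheme,
    TangentUndefinedError,
    project_template,
    slide_once,
    slide_sample,
)
from patellamorph.surface import SurfaceMesh
from patellamorph.synthetic import make_template
from patellamorph.tps import bending_energy, bending_energy_matrix


@pytest.fixture(scope="module")
def template():
    return make_template(n_curve=20, n_surface=40)


@pytest.fixture(scope="module")
def scheme(template):
    return SlidingScheme.from_configuration(template.config)


def _rigid(points, rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return points @ R + rng.uniform(-3, 3, 3), R


class TestProjectTemplate:
    def test_identity_specimen(self, template):
        cfg, mesh = template.config, template.mesh
        anchors = cfg.subset(cfg.classes != "surface")
        out = project_template(cfg, mesh, anchors, mesh)
        np.testing.assert_allclose(out.points, cfg.points, atol=1e-8)

    def test_rigid_equivariance(self, template, rng):
        cfg, mesh = template.config, template.mesh
        moved, R = _rigid(cfg.points, rng)
        shift = moved - cfg.points @ R  # the translation actually applied
        mesh2 = SurfaceMesh(mesh.vertices @ R + shift[0], mesh.faces.copy())
        anchors = cfg.subset(cfg.classes != "surface").with_points(
            moved[cfg.classes != "surface"])
        out = project_template(cfg, mesh, anchors, mesh2)
        np.testing.assert_allclose(out.points, moved, atol=1e-6)

    def test_projected_points_lie_on_specimen_mesh(self, template):
        """Ellipsoid-like pair: template at one medial angle, specimen at another."""
        other = make_template(n_curve=20, n_surface=40, medial_angle=0.2)
        anchors = other.config.subset(other.config.classes != "surface")
        out = project_template(template.config, template.mesh, anchors, other.mesh)
        surf = out.points[out.classes == "surface"]
        _, _, d = other.mesh.closest_points(surf)
        assert d.max() <= 1e-9 * other.mesh.scale

    def test_anchor_count_mismatch(self, template):
        cfg, mesh = template.config, template.mesh
        bad = cfg.subset(cfg.classes == "anatomical")   # missing the curves
        with pytest.raises(ValueError, match="mismatch"):
            project_template(cfg, mesh, bad, mesh)


class TestSlideOnce:
    def test_reference_equals_config_is_identity(self, template, scheme):
        cfg, mesh = template.config, template.mesh
        out = slide_once(cfg, cfg, mesh, scheme)
        np.testing.assert_allclose(out.points, cfg.points, atol=1e-9)

    def test_energy_decreases_for_tangent_perturbation(self, template, scheme, rng):
        cfg, mesh = template.config, template.mesh
        ref = cfg.with_points(cfg.points + 0.02 * rng.standard_normal(cfg.points.shape))
        out = slide_once(cfg, ref, mesh, scheme)
        e_before = bending_energy(ref.points, cfg.points)
        e_after = bending_energy(ref.points, out.points)
        assert e_after <= e_before + 1e-9
        assert e_after < e_before  # strictly better on a generic perturbation

    def test_anatomical_landmarks_bitwise_immobile(self, template, scheme, rng):
        cfg, mesh = template.config, template.mesh
        ref = cfg.with_points(cfg.points + 0.02 * rng.standard_normal(cfg.points.shape))
        out = slide_once(cfg, ref, mesh, scheme)
        np.testing.assert_array_equal(out.points[scheme.anatomical_ids],
                                      cfg.points[scheme.anatomical_ids])

    def test_surface_points_stay_on_mesh(self, template, scheme, rng):
        cfg, mesh = template.config, template.mesh
        ref = cfg.with_points(cfg.points + 0.03 * rng.standard_normal(cfg.points.shape))
        out = slide_once(cfg, ref, mesh, scheme)
        _, _, d = mesh.closest_points(out.points[scheme.surface_ids])
        assert d.max() <= 1e-9 * mesh.scale

    def test_matches_brute_force_grid_oracle(self, rng):
        """Restricted minimiser vs exhaustive grid search, 2 sliding points.

        10 landmarks: 6 anatomical + one 4-point curve whose endpoints are
        pinned, leaving exactly two tangential degrees of freedom.
        """
        anat = np.array([
            [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [1, 1, 0.2], [0.5, -0.8, 0.6],
        ], dtype=float)
        curve = np.array([
            [0.0, 0.4, 1.2], [0.35, 0.42, 1.25], [0.7, 0.44, 1.22], [1.05, 0.4, 1.15],
        ])
        pts = np.vstack([anat, curve])
        classes = np.array(["anatomical"] * 6 + ["curve"] * 4, dtype=object)
        cids = np.array([-1] * 6 + [0] * 4)
        cfg = LandmarkConfiguration("toy", pts, classes, cids)
        scheme = SlidingScheme(np.arange(6), [np.arange(6, 10)], np.array([]),
                               fixed_ids=np.array([6, 9]))
        ref = cfg.with_points(pts + 0.03 * rng.standard_normal(pts.shape))

        out = slide_once(cfg, ref, None, scheme, reproject=False)
        e_slid = bending_energy(ref.points, out.points)

        # oracle: exhaustive search over the two tangent offsets
        B = bending_energy_matrix(ref.points)

        def tangent(i):
            chord = pts[i + 1] - pts[i - 1]
            return chord / np.linalg.norm(chord)

        t7, t8 = tangent(7), tangent(8)
        offsets = np.arange(-0.05, 0.05 + 1e-12, 1e-3)
        best = np.inf
        for o7 in offsets:
            for o8 in offsets:
                trial = pts.copy()
                trial[7] += o7 * t7
                trial[8] += o8 * t8
                e = float(np.einsum("id,ij,jd->", trial, B, trial))
                best = min(best, e)
        assert e_slid <= best + 1e-6
        assert e_slid == pytest.approx(best, abs=2e-3 * abs(best) + 1e-8)

    def test_coincident_curve_neighbours_error(self):
        pts = np.array([
            [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [0.5, 0.5, 1.0], [0.5, 0.5, 1.0 + 1e-15], [0.9, 0.5, 1.0],
        ])
        classes = np.array(["anatomical"] * 4 + ["curve"] * 3, dtype=object)
        cids = np.array([-1] * 4 + [0] * 3)
        cfg = LandmarkConfiguration("bad", pts, classes, cids)
        scheme = SlidingScheme(np.arange(4), [np.arange(4, 7)], np.array([]))
        ref = cfg.with_points(pts + np.array([0, 0, 0.5]))
        with pytest.raises(TangentUndefinedError):
            slide_once(cfg, ref, None, scheme)


class TestSlideSample:
    def test_identical_configurations_unchanged(self, template, scheme):
        cfg, mesh = template.config, template.mesh
        sample = ShapeSample([cfg.with_points(cfg.points.copy()) for _ in range(4)])
        for i, c in enumerate(sample.configurations):
            c.specimen_id = f"s{i}"
        meshes = {f"s{i}": mesh for i in range(4)}
        out = slide_sample(sample, cfg, meshes, scheme)
        for c in out.configurations:
            np.testing.assert_allclose(c.points, cfg.points, atol=1e-7)

    def test_energy_non_increasing_and_deterministic(self, template, scheme, rng):
        cfg, mesh = template.config, template.mesh
        configs, meshes = [], {}
        for i in range(6):
            pts = cfg.points + 0.02 * rng.standard_normal(cfg.points.shape)
            pts[:6] = cfg.points[:6]  # keep anchors sane
            configs.append(LandmarkConfiguration(f"s{i}", pts, cfg.classes,
                                                 cfg.curve_ids))
            meshes[f"s{i}"] = mesh
        sample = ShapeSample(configs)
        out1 = slide_sample(sample, cfg, meshes, scheme)
        energies = out1.provenance["mean_bending_energy_per_pass"]
        assert len(energies) == 1 + scheme.n_consensus_iterations
        consensus_passes = np.array(energies[1:])
        assert np.all(np.diff(consensus_passes) <= 1e-9)
        # determinism: an identical rerun reproduces every coordinate bitwise
        out2 = slide_sample(sample, cfg, meshes, scheme)
        for a, b in zip(out1.configurations, out2.configurations):
            np.testing.assert_array_equal(a.points, b.points)

    def test_zero_consensus_iterations_single_pass(self, template, rng):
        cfg, mesh = template.config, template.mesh
        scheme0 = SlidingScheme.from_configuration(cfg, n_consensus_iterations=0)
        pts = cfg.points + 0.01 * rng.standard_normal(cfg.points.shape)
        sample = ShapeSample([LandmarkConfiguration("a", pts, cfg.classes, cfg.curve_ids),
                              LandmarkConfiguration("b", pts.copy(), cfg.classes,
                                                    cfg.curve_ids)])
        out = slide_sample(sample, cfg, {"a": mesh, "b": mesh}, scheme0)
        assert out.provenance["n_passes"] == 1
        assert len(out.provenance["mean_bending_energy_per_pass"]) == 1
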