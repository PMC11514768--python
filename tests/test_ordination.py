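"""PCA structure, theoretical shapes, mesh warping, and NJ tree recovery."""

import numpy as np
import pytest

from patellamorph.landmark_io import LandmarkConfiguration, ShapeSample
from patellamorph.ordination import (
    displacement_field,
    mesh_deformation_scalars,
    nj_from_distance_matrix,
    nj_tree,
    pca,
    theoretical_shape,
    warp_mesh,
)
from patellamorph.procrustes import gpa


def _sample(rng, n=8, k=7, noise=0.1):
    base = rng.standard_normal((k, 3))
    cfgs = [LandmarkConfiguration(f"s{i}", base + noise * rng.standard_normal((k, 3)))
            for i in range(n)]
    return gpa(ShapeSample(cfgs))


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return D, [t.label for t in taxa]


def _splits(tree):
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        labs = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(labs) < len(all_leaves) - 1:
            other = all_leaves - labs
            out.add(labs if len(labs) <= len(other) else other)
    return out


class TestPca:
    def test_single_direction_gives_pc1_all_variance(self, rng):
        from patellamorph.procrustes import AlignedSample
        base = rng.standard_normal((6, 3))
        v = rng.standard_normal((6, 3))
        arr = np.stack([base + t * v for t in np.linspace(-0.1, 0.1, 6)])
        cfgs = [LandmarkConfiguration(f"s{i}", arr[i]) for i in range(6)]
        al = AlignedSample(ShapeSample(cfgs), arr, arr.mean(axis=0), np.ones(6))
        o = pca(al)
        assert o.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_completeness(self, rng):
        al = _sample(rng)
        o = pca(al)
        recon = o.consensus.ravel() + o.scores @ o.eigenvectors
        np.testing.assert_allclose(recon, al.flattened(), atol=1e-8)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        """Eigenvalues must equal those of the covariance of the residuals."""
        al = _sample(rng)
        o = pca(al)
        X = al.flattened() - al.consensus.ravel()
        w = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        np.testing.assert_allclose(o.eigenvalues, w[:o.n_axes], rtol=1e-8, atol=1e-12)

    def test_invariants(self, rng):
        al = _sample(rng)
        o = pca(al)
        assert o.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(o.scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(o.eigenvectors @ o.eigenvectors.T,
                                   np.eye(o.n_axes), atol=1e-10)

    def test_rotation_invariance_of_eigenvalues(self, rng):
        al = _sample(rng)
        o1 = pca(al)
        # rotate every aligned configuration by one common orthogonal matrix
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        al2 = _sample(rng, n=2)  # reuse the dataclass shell
        al2 = type(al)(al.sample, al.aligned @ q, al.consensus @ q,
                       al.centroid_sizes)
        o2 = pca(al2)
        np.testing.assert_allclose(o2.eigenvalues, o1.eigenvalues, rtol=1e-8)

    def test_needs_three_specimens(self, rng):
        with pytest.raises(ValueError):
            pca(_sample(rng, n=2))


class TestTheoreticalShape:
    def test_zero_score_is_consensus(self, rng):
        o = pca(_sample(rng))
        np.testing.assert_array_equal(theoretical_shape(o, 0, 0.0).points, o.consensus)

    def test_rank_one_approximation(self, rng):
        al = _sample(rng)
        o = pca(al)
        s0 = o.scores[2, 0]
        shape = theoretical_shape(o, 0, float(s0))
        expected = o.consensus.ravel() + s0 * o.eigenvectors[0]
        np.testing.assert_allclose(shape.points.ravel(), expected, atol=1e-12)

    def test_plus_minus_symmetry(self, rng):
        o = pca(_sample(rng))
        hi = theoretical_shape(o, 1, 0.3).points
        lo = theoretical_shape(o, 1, -0.3).points
        np.testing.assert_allclose(hi + lo, 2 * o.consensus, atol=1e-12)

    def test_axis_out_of_range(self, rng):
        o = pca(_sample(rng))
        with pytest.raises(IndexError):
            theoretical_shape(o, o.n_axes + 3, 0.1)


class TestDisplacementField:
    def test_trivial_cases(self, rng):
        a = rng.standard_normal((6, 3))
        d, norm = displacement_field(a, a)
        assert d.max() == 0.0 and norm.max() == 0.0
        b = a.copy()
        b[2] += np.array([0, 0, 1.0])
        d, norm = displacement_field(a, b)
        assert d[2] == pytest.approx(1.0)
        assert np.count_nonzero(d) == 1
        assert norm[2] == 1.0


class TestWarpMesh:
    def test_identity_and_affine(self, small_template, rng):
        cfg, mesh = small_template.config, small_template.mesh
        same = warp_mesh(mesh, cfg, cfg)
        np.testing.assert_allclose(same.vertices, mesh.vertices, atol=1e-8)
        A = np.diag([1.3, 0.8, 1.1])
        b = np.array([1.0, 0.0, -2.0])
        target = cfg.with_points(cfg.points @ A + b)
        warped = warp_mesh(mesh, cfg, target)
        np.testing.assert_allclose(warped.vertices, mesh.vertices @ A + b, atol=1e-8)

    def test_warped_mesh_tracks_target_landmarks(self, small_template, rng):
        """After warping, the mesh must hug the target landmarks as tightly as
        the template mesh hugs the template landmarks (nearest-point oracle)."""
        cfg, mesh = small_template.config, small_template.mesh
        target = cfg.with_points(
            cfg.points + 0.05 * rng.standard_normal(cfg.points.shape))
        warped = warp_mesh(mesh, cfg, target)
        _, _, d_before = mesh.closest_points(cfg.points)
        _, _, d_after = warped.closest_points(target.points)
        assert d_after.max() <= d_before.max() + 0.02 * mesh.scale

    def test_deformation_scalars_signed_and_magnitude(self, small_template):
        cfg, mesh = small_template.config, small_template.mesh
        inflated = warp_mesh(mesh, cfg, cfg.with_points(cfg.points * 1.1))
        signed = mesh_deformation_scalars(mesh, inflated, signed=True)
        mag = mesh_deformation_scalars(mesh, inflated, signed=False)
        assert (mag >= 0).all()
        assert np.mean(signed > 0) > 0.9      # inflation points outward


class TestNeighbourJoining:
    def test_recovers_additive_four_leaf_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_from_distance_matrix(D, labels)
        assert frozenset({"A", "B"}) in _splits(tree)
        D_hat, labs = _patristic(tree)
        order = [labs.index(x) for x in labels]
        np.testing.assert_allclose(D_hat[np.ix_(order, order)], D, atol=1e-10)

    def test_square_corners_topology_matches_ls_oracle(self):
        """Four specimens at square corners: NJ must pair adjacent corners,
        matching the best least-squares fit over all three topologies."""
        scores = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        diff = scores[:, None] - scores[None, :]
        D = np.sqrt((diff ** 2).sum(-1))

        def ls_error(pairing):
            # topology (ab|cd): least-squares branch lengths, constrained >= 0
            from scipy.optimize import nnls
            (a, b), (c, d) = pairing
            A, y = [], []
            for i in range(4):
                for j in range(i + 1, 4):
                    row = [0.0] * 5
                    row[i] = row[j] = 1.0
                    same = {i, j} in ({a, b}, {c, d})
                    if not same:
                        row[4] = 1.0
                    A.append(row)
                    y.append(D[i, j])
            _, rnorm = nnls(np.array(A), np.array(y))
            return float(rnorm ** 2)

        topologies = {((0, 1), (2, 3)): "adjacent01",
                      ((0, 3), (1, 2)): "adjacent03",
                      ((0, 2), (1, 3)): "diagonal"}
        errors = {name: ls_error(p) for p, name in topologies.items()}
        best = {n for n, e in errors.items()
                if e <= min(errors.values()) + 1e-9}
        assert "diagonal" not in best  # diagonal pairing is strictly worse

        tree = nj_tree(scores, ["c0", "c1", "c2", "c3"])
        splits = _splits(tree)
        assert frozenset({"c0", "c2"}) not in splits
        assert frozenset({"c1", "c3"}) not in splits

    def test_scaling_scores_scales_branch_lengths(self, rng):
        scores = rng.standard_normal((6, 4))
        t1 = nj_tree(scores, [f"s{i}" for i in range(6)])
        t2 = nj_tree(3.0 * scores, [f"s{i}" for i in range(6)])
        d1, labs = _patristic(t1)
        d2, _ = _patristic(t2)
        np.testing.assert_allclose(d2, 3.0 * d1, rtol=1e-10)

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Independent cross-check: scikit-bio's NJ finds the same topology."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        labels = ["A", "B", "C", "D", "E"]
        # additive distances from ((A:1,B:1):3,(C:2,(D:1,E:2):1):1)
        D = np.array([
            [0, 2, 7, 7, 8],
            [2, 0, 7, 7, 8],
            [7, 7, 0, 4, 5],
            [7, 7, 4, 0, 3],
            [8, 8, 5, 3, 0],
        ], dtype=float)
        ours = _splits(nj_from_distance_matrix(D, labels))
        sk = skbio_nj(DistanceMatrix(D, labels))
        sk_tree = __import__("dendropy").Tree.get(data=str(sk), schema="newick")
        assert ours == _splits(sk_tree)

    def test_duplicate_specimens_zero_cherry(self):
        scores = np.array([[0.0, 0], [0, 0], [3, 0], [0, 4]])
        tree = nj_tree(scores, ["a", "a2", "b", "c"])
        D, labs = _patristic(tree)
        i, j = labs.index("a"), labs.index("a2")
        assert D[i, j] == pytest.approx(0.0, abs=1e-10)

    def test_needs_four(self, rng):
        with pytest.raises(ValueError):
            nj_tree(rng.standard_normal((3, 2)), ["a", "b", "c"])
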