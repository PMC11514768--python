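"""Correlation tests, PERMANOVA vs classical ANOVA oracles, Procrustes ANOVA."""

import numpy as np
import pytest
from itertools import permutations as iter_permutations

from scipy import stats as sps

from patellamorph.landmark_io import LandmarkConfiguration, ShapeSample
from patellamorph.procrustes import gpa
from patellamorph.stats import (
    allometric_shapes,
    pearson_test,
    permanova,
    predicted_shape,
    procrustes_anova,
    significance_flag,
)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        """x=(1,2,3), y=(1,2,4): r = 3/sqrt(2*14/3), t = 3*sqrt(3), Cauchy p."""
        res = pearson_test([1, 2, 3], [1, 2, 4])
        r_oracle = 3.0 / np.sqrt(2.0 * 14.0 / 3.0)
        assert res.r == pytest.approx(r_oracle, abs=1e-10)
        assert res.r == pytest.approx(0.9820, abs=5e-5)
        assert res.df == 1
        assert res.t == pytest.approx(3 * np.sqrt(3), rel=1e-10)
        # df=1 Student t is Cauchy: p = 2*(0.5 - atan(t)/pi)
        p_oracle = 2 * (0.5 - np.arctan(3 * np.sqrt(3)) / np.pi)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_t_r_identity(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = pearson_test(x, y)
        assert res.t == pytest.approx(
            res.r * np.sqrt(res.df / (1 - res.r ** 2)), abs=1e-10)
        assert res.df == 28

    def test_matches_scipy(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        res = pearson_test(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_output_schema(self):
        df = pearson_test([1, 2, 3, 4], [1, 3, 2, 4]).to_frame()
        assert list(df.columns) == ["r", "t", "dF", "P"]


class TestPermanova:
    def test_univariate_toy_sums_of_squares(self):
        """(1,2,3,4) vs (A,A,B,B): SS_factor=4, SS_resid=1, R2=0.8, F=8."""
        tab = permanova(np.array([1.0, 2, 3, 4]), [["A", "A", "B", "B"]],
                        n_permutations=9, seed=0, factor_names=["g"])
        row = tab["g"]
        assert row.ss == pytest.approx(4.0, abs=1e-12)
        assert tab["Residuals"].ss == pytest.approx(1.0, abs=1e-12)
        assert tab.total_ss == pytest.approx(5.0, abs=1e-12)
        assert row.r2 == pytest.approx(0.8, abs=1e-12)
        assert row.f == pytest.approx(8.0, abs=1e-12)

    def test_exact_enumeration_p_one_third(self):
        """Full enumeration of the 24 row permutations gives exactly p = 1/3."""
        perms = [list(p) for p in iter_permutations(range(4))]
        tab = permanova(np.array([1.0, 2, 3, 4]), [["A", "A", "B", "B"]],
                        permutation_set=perms, factor_names=["g"])
        assert tab["g"].p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_level_after_exclusion_errors(self):
        with pytest.raises(ValueError, match="single level"):
            permanova(np.arange(4.0), [["A", "A", "A", "A"]], n_permutations=9)
        with pytest.raises(ValueError, match="single level"):
            permanova(np.arange(4.0), [["A", "A", "A", None]], n_permutations=9)

    def test_missing_rows_excluded_and_counted(self, rng):
        y = rng.standard_normal((10, 2))
        f = ["A"] * 5 + ["B"] * 3 + [None, None]
        tab = permanova(y, [f], n_permutations=9, seed=0)
        assert tab.n_excluded == 2
        assert tab.total_df == 7

    def test_matches_classical_anova_on_50_toys(self, rng):
        """One-factor univariate PERMANOVA F == textbook one-way ANOVA F."""
        for _ in range(50):
            n_groups = rng.integers(2, 5)
            sizes = rng.integers(3, 7, n_groups)
            y = rng.standard_normal(int(sizes.sum()))
            labels = np.repeat([f"g{i}" for i in range(n_groups)], sizes)
            tab = permanova(y, [labels], n_permutations=0, seed=0)
            groups = [y[labels == f"g{i}"] for i in range(n_groups)]
            f_oracle = sps.f_oneway(*groups).statistic
            assert tab.rows[0].f == pytest.approx(f_oracle, rel=1e-10)

    def test_sequential_ss_total_invariant_under_order(self, rng):
        y = rng.standard_normal((20, 3))
        f1 = list(rng.choice(["a", "b", "c"], 20))
        f2 = list(rng.choice(["x", "y"], 20))
        t12 = permanova(y, [f1, f2], n_permutations=0, seed=0)
        t21 = permanova(y, [f2, f1], n_permutations=0, seed=0)
        assert t12.total_ss == pytest.approx(t21.total_ss, rel=1e-10)
        # sequential: per-term SS may differ, residual identical
        assert t12["Residuals"].ss == pytest.approx(t21["Residuals"].ss, rel=1e-10)

    def test_r2_rows_sum_to_one(self, rng):
        y = rng.standard_normal((15, 4))
        f = list(rng.choice(["a", "b", "c"], 15))
        tab = permanova(y, [f], n_permutations=19, seed=1)
        assert sum(r.r2 for r in tab.rows) == pytest.approx(1.0, abs=1e-8)
        assert sum(r.df for r in tab.rows) == tab.total_df


def _aligned_from_flat(base, rows, rng):
    """AlignedSample built in place: the rows ARE the tangent-space coordinates."""
    from patellamorph.procrustes import AlignedSample
    arr = np.stack([(base.ravel() + r).reshape(-1, 3) for r in rows])
    cfgs = [LandmarkConfiguration(f"s{i}", arr[i]) for i in range(len(arr))]
    sample = ShapeSample(cfgs)
    return AlignedSample(sample, arr, arr.mean(axis=0), np.ones(len(arr)))


class TestProcrustesAnova:
    def _planted(self, rng, n=20, k=8, rho_noise=0.0):
        """Shapes = base + beta*(x - mean)*v (+ noise); returns (aligned, x, v)."""
        base = rng.standard_normal((k, 3))
        base /= np.sqrt((base - base.mean(0)).__pow__(2).sum())
        v = rng.standard_normal(3 * k)
        v /= np.linalg.norm(v)
        x = rng.uniform(0, 1, n)
        rows = [0.05 * (xi - x.mean()) * v + rho_noise * rng.standard_normal(3 * k)
                for xi in x]
        return _aligned_from_flat(base, rows, rng), x

    def test_pure_allometry_r2_one(self, rng):
        al, x = self._planted(rng)
        tab = procrustes_anova(al, x, n_permutations=99, seed=0)
        assert tab.rows[0].r2 > 1 - 1e-6
        assert tab.rows[0].p == pytest.approx(1.0 / 100.0)  # smallest attainable

    def test_r2_matches_multivariate_ols_oracle(self, rng):
        """Procrustes SS and tangent-space Euclidean SS coincide, so R2 must
        equal the R2 of ordinary multivariate regression of the flattened
        aligned coordinates on the covariate."""
        al, x = self._planted(rng, rho_noise=0.01)
        tab = procrustes_anova(al, x, n_permutations=0, seed=0)
        Y = al.flattened()
        X = np.column_stack([np.ones_like(x), x])
        _, res, *_ = np.linalg.lstsq(X, Y, rcond=None)
        ss_resid = float(res.sum())
        Yc = Y - Y.mean(axis=0)
        r2_oracle = 1 - ss_resid / float((Yc ** 2).sum())
        assert tab.rows[0].r2 == pytest.approx(r2_oracle, abs=1e-8)

    def test_missing_covariate_excluded(self, rng):
        al, x = self._planted(rng, n=12, rho_noise=0.01)
        cov = list(x)
        cov[0] = None
        cov[5] = float("nan")
        tab = procrustes_anova(al, cov, n_permutations=9, seed=0)
        assert tab.n_excluded == 2
        assert tab.total_df == 9
        assert tab.rows[1].df == 8   # mirrors the fewer-Df FC analysis

    def test_constant_covariate_errors(self, rng):
        al, _ = self._planted(rng, n=6)
        with pytest.raises(ValueError, match="constant"):
            procrustes_anova(al, np.ones(6), n_permutations=9)

    def test_z_score_large_for_strong_effect(self, rng):
        al, x = self._planted(rng, rho_noise=0.001)
        tab = procrustes_anova(al, x, n_permutations=199, seed=3)
        assert tab.rows[0].z > 2.0

    def test_table_schema_matches_report_layout(self, rng):
        al, x = self._planted(rng, rho_noise=0.01)
        tab = procrustes_anova(al, x, n_permutations=19, seed=0, term="log CS")
        df = tab.to_frame()
        assert list(df.columns) == ["term", "Df", "SS", "R2", "F", "Z", "P", "flag"]
        assert list(df["term"]) == ["log CS", "Residuals", "Total"]
        assert df["Df"].iloc[:2].sum() == tab.total_df


class TestAllometricShapes:
    def test_pure_toy_extremes_on_planted_line(self, rng):
        base = rng.standard_normal((8, 3))
        v = rng.standard_normal(24)
        v /= np.linalg.norm(v)
        x = np.linspace(0.0, 1.0, 10)
        rows = [0.05 * (xi - x.mean()) * v for xi in x]
        al = _aligned_from_flat(base, rows, rng)
        tab = procrustes_anova(al, x, n_permutations=9, seed=0)
        lo, hi = allometric_shapes(tab)
        Y = al.flattened()
        np.testing.assert_allclose(lo.points.ravel(), Y[0], atol=1e-6)
        np.testing.assert_allclose(hi.points.ravel(), Y[-1], atol=1e-6)

    def test_zero_slope_gives_consensus_twice(self, rng):
        base = rng.standard_normal((8, 3))
        rows = [np.zeros(24) for _ in range(6)]   # constant shape
        al = _aligned_from_flat(base, rows, rng)
        tab = procrustes_anova(al, np.arange(6.0), n_permutations=9, seed=0)
        lo, hi = allometric_shapes(tab)
        np.testing.assert_allclose(lo.points, hi.points, atol=1e-10)
        np.testing.assert_allclose(lo.points.ravel(), al.flattened().mean(axis=0),
                                   atol=1e-10)

    def test_midpoint_linearity(self, rng):
        base = rng.standard_normal((8, 3))
        v = rng.standard_normal(24)
        x = np.linspace(0.0, 1.0, 8)
        rows = [0.03 * (xi - x.mean()) * v for xi in x]
        al = _aligned_from_flat(base, rows, rng)
        tab = procrustes_anova(al, x, n_permutations=9, seed=0)
        lo, hi = allometric_shapes(tab)
        mid = predicted_shape(tab, float((x.min() + x.max()) / 2))
        np.testing.assert_allclose(mid.points, (lo.points + hi.points) / 2, atol=1e-10)


class TestSignificanceConvention:
    def test_flags(self):
        assert significance_flag(0.04) == "significant"
        assert significance_flag(0.05) == "significant"
        assert significance_flag(0.07) == "marginal"
        assert significance_flag(0.10) == "marginal"
        assert significance_flag(0.2) == "ns"
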