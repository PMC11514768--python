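"""Permutational shape statistics and correlation tests.

Three inferential tools drive the analysis:

* Pearson correlation (PC scores vs log centroid size) with the exact
  t-reference distribution;
* PERMANOVA on PC scores with sequential (Type-I) sums of squares under the
  Euclidean metric, p-values by free permutation of specimen rows;
* permutational Procrustes ANOVA — a linear model of shape on a size covariate
  whose sums of squares are squared Procrustes (= tangent-space Euclidean)
  distances, with residual randomization (RRPP) p-values and effect sizes Z
  computed on log F.

Significance convention: p <= 0.05 is flagged significant and 0.05 < p <= 0.10
marginal.  Missing data are handled by listwise exclusion, never imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmark_io import LandmarkConfiguration
from .procrustes import AlignedSample

__all__ = [
    "CorrelationResult",
    "AnovaTable",
    "pearson_test",
    "permanova",
    "procrustes_anova",
    "allometric_shapes",
]


def significance_flag(p: float) -> str:
    if p <= 0.05:
        return "significant"
    if p <= 0.10:
        return "marginal"
    return "ns"


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float

    @property
    def flag(self) -> str:
        return significance_flag(self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"r": self.r, "t": self.t, "dF": self.df, "P": self.p}])


@dataclass
class AnovaRow:
    term: str
    df: int
    ss: float
    r2: float | None
    f: float | None
    z: float | None
    p: float | None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    total_ss: float
    total_df: int
    n_permutations: int
    seed: int | None
    n_excluded: int = 0
    extras: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        recs = [{"term": r.term, "Df": r.df, "SS": r.ss, "R2": r.r2,
                 "F": r.f, "Z": r.z, "P": r.p,
                 "flag": significance_flag(r.p) if r.p is not None else ""}
                for r in self.rows]
        recs.append({"term": "Total", "Df": self.total_df, "SS": self.total_ss,
                     "R2": 1.0, "F": None, "Z": None, "P": None, "flag": ""})
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_permutations: {self.n_permutations}\n")
            fh.write(f"# seed: {self.seed}\n")
            if self.n_excluded:
                fh.write(f"# specimens_excluded: {self.n_excluded}\n")
            self.to_frame().to_csv(fh, index=False)


def pearson_test(x, y) -> CorrelationResult:
    """Two-sided Pearson test; p from the t distribution with n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), t=float(np.sign(r) * np.inf),
                                 df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, t=float(t), df=df, p=float(p))


# ------------------------------------------------------------------- PERMANOVA
def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def _dummy(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment coding for one factor (first level dropped)."""
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _hat(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300))
    q = q[:, :rank]
    return q @ q.T


def _sequential_f(Y: np.ndarray, factor_arrays: list[np.ndarray]):
    """Sequential SS/F for each term; returns (ss_terms, df_terms, ss_resid, df_resid, F)."""
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    ones = np.ones((n, 1))
    design = ones
    prev_hat = _hat(design)
    ss_terms, df_terms = [], []
    for fac in factor_arrays:
        design = np.hstack([design, _dummy(fac)])
        h = _hat(design)
        delta = h - prev_hat
        ss_terms.append(float(np.einsum("ij,jk,ki->", Y.T, delta, Y)))
        df_terms.append(int(round(np.trace(delta))))
        prev_hat = h
    ss_model = sum(ss_terms)
    df_model = sum(df_terms)
    df_resid = n - 1 - df_model
    ss_resid = ss_total - ss_model
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom after fitting all terms")
    F = np.array([(sst / dft) / (ss_resid / df_resid) if dft > 0 else np.nan
                  for sst, dft in zip(ss_terms, df_terms)])
    return np.array(ss_terms), np.array(df_terms), ss_resid, df_resid, ss_total, F


def permanova(response: np.ndarray, factors, n_permutations: int = 999,
              seed: int | None = None, factor_names: list[str] | None = None,
              permutation_set: list | None = None) -> AnovaTable:
    """Euclidean-distance PERMANOVA with sequential (order-dependent) SS.

    ``factors`` is an ordered list of per-specimen label sequences; rows with a
    missing level (None/NaN) in any factor are excluded first (count recorded
    on the result).  p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under
    free permutation of specimen rows.  Passing ``permutation_set`` (an
    explicit, exhaustive list of row permutations, including the identity)
    switches to the exact convention p = #{F_perm >= F_obs} / |set|.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    factors = [np.asarray(list(f), dtype=object) for f in factors]
    if factor_names is None:
        factor_names = [f"factor{i + 1}" for i in range(len(factors))]
    n = len(Y)
    keep = np.ones(n, dtype=bool)
    for fac in factors:
        if len(fac) != n:
            raise ValueError("factor length mismatch")
        keep &= ~np.array([_is_missing(v) for v in fac])
    n_excluded = int(n - keep.sum())
    Y = Y[keep]
    factors = [f[keep] for f in factors]
    n = len(Y)
    for name, fac in zip(factor_names, factors):
        if len(pd.unique(fac)) < 2:
            raise ValueError(f"factor {name!r} has a single level after exclusion")

    ss_terms, df_terms, ss_resid, df_resid, ss_total, F_obs = _sequential_f(Y, factors)

    exceed = np.zeros(len(factors))
    if permutation_set is not None:
        for perm in permutation_set:
            _, _, _, _, _, F_perm = _sequential_f(Y[np.asarray(perm)], factors)
            exceed += F_perm >= F_obs - 1e-12
        p = exceed / len(permutation_set)
        n_permutations = len(permutation_set)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            _, _, _, _, _, F_perm = _sequential_f(Y[perm], factors)
            exceed += F_perm >= F_obs - 1e-12
        p = (1.0 + exceed) / (1.0 + n_permutations)

    rows = [AnovaRow(term=name, df=int(dft), ss=float(sst),
                     r2=float(sst / ss_total), f=float(f), z=None, p=float(pv))
            for name, dft, sst, f, pv in zip(factor_names, df_terms, ss_terms, F_obs, p)]
    rows.append(AnovaRow("Residuals", int(df_resid), float(ss_resid),
                         float(ss_resid / ss_total), None, None, None))
    return AnovaTable(rows, total_ss=float(ss_total), total_df=n - 1,
                      n_permutations=n_permutations, seed=seed, n_excluded=n_excluded)


# ------------------------------------------------------------- Procrustes ANOVA
def procrustes_anova(aligned: AlignedSample, covariate, n_permutations: int = 1000,
                     seed: int | None = None, term: str = "covariate") -> AnovaTable:
    """Permutational regression of shape on one continuous covariate.

    Sums of squares are squared Procrustes distances between observed and
    fitted shapes (identical to tangent-space Euclidean SS); inference uses
    residual randomization under the reduced (intercept-only) model, with
    p = (1 + b) / (1 + m) and effect size Z = standardised log F.  Specimens
    whose covariate is missing are excluded (count recorded).
    """
    x_all = np.asarray([np.nan if _is_missing(v) else float(v) for v in covariate])
    if len(x_all) != aligned.n:
        raise ValueError("one covariate value per specimen required")
    keep = np.isfinite(x_all)
    n_excluded = int((~keep).sum())
    Y = aligned.flattened()[keep]
    x = x_all[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 specimens with a covariate value")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    beta = (xc @ Yc) / (xc @ xc)            # (3k,) slope vector
    fitted_c = np.outer(xc, beta)
    ss_model = float((fitted_c ** 2).sum())
    ss_resid = max(ss_total - ss_model, 0.0)
    df_model, df_resid = 1, n - 2

    def f_ratio(ssm: float, ssr: float) -> float:
        if ssr <= 1e-14 * max(ssm, 1.0):
            return np.inf
        return (ssm / df_model) / (ssr / df_resid)

    F_obs = f_ratio(ss_model, ss_resid)

    rng = np.random.default_rng(seed)
    F_perm = np.empty(n_permutations)
    exceed = 0
    for b in range(n_permutations):
        Yp = Yc[rng.permutation(n)]         # RRPP, reduced model = intercept
        bp = (xc @ Yp) / (xc @ xc)
        ssm = float(np.outer(xc, bp).__pow__(2).sum())
        ssr = max(float((Yp ** 2).sum()) - ssm, 0.0)
        F_perm[b] = f_ratio(ssm, ssr)
        if F_perm[b] >= F_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    finite = np.isfinite(F_perm) & (F_perm > 0)
    if np.isfinite(F_obs) and finite.sum() >= 2:
        logs = np.log(F_perm[finite])
        sd = np.log(np.append(F_perm[finite], F_obs)).std(ddof=1)
        z = (np.log(F_obs) - logs.mean()) / sd if sd > 0 else np.inf
    else:
        z = np.inf

    rows = [
        AnovaRow(term, df_model, ss_model, ss_model / ss_total, F_obs, float(z), float(p)),
        AnovaRow("Residuals", df_resid, ss_resid, ss_resid / ss_total, None, None, None),
    ]
    table = AnovaTable(rows, total_ss=ss_total, total_df=n - 1,
                       n_permutations=n_permutations, seed=seed, n_excluded=n_excluded)
    table.extras.update({
        "mean_shape": Y.mean(axis=0), "beta": beta,
        "x": x, "x_mean": x.mean(),
        "fitted_values": x,  # predictor values at which shapes were fitted
        "k": aligned.k,
        "classes": aligned.sample.configurations[0].classes,
        "curve_ids": aligned.sample.configurations[0].curve_ids,
    })
    return table


def predicted_shape(table: AnovaTable, value: float) -> LandmarkConfiguration:
    """Model-predicted shape at a given covariate value."""
    ex = table.extras
    flat = ex["mean_shape"] + (value - ex["x_mean"]) * ex["beta"]
    return LandmarkConfiguration(f"fitted@{value:g}", flat.reshape(-1, 3),
                                 ex["classes"], ex["curve_ids"])


def allometric_shapes(table: AnovaTable) -> tuple[LandmarkConfiguration, LandmarkConfiguration]:
    """Predicted shapes at the minimal and maximal fitted covariate values.

    Feeding the pair to ``displacement_field`` / ``warp_mesh`` reproduces the
    allometric deformation colour-map workflow.
    """
    if "beta" not in table.extras:
        raise ValueError("table does not carry a fitted shape regression")
    x = table.extras["x"]
    return predicted_shape(table, float(x.min())), predicted_shape(table, float(x.max()))
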