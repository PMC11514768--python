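"""Phylogenetic signal: Brownian-motion simulation, Blomberg's K and Kmult.

K compares the observed ratio of mean squared error about the phylogenetic
(GLS) mean to the GLS mean squared error against the same ratio expected
under Brownian motion on the tree:

    K = [MSE0 / MSE] / [(tr C - N / sum(C^-1)) / (N - 1)]

with C the Brownian covariance (shared root-to-MRCA path lengths).  K = 1 is
the Brownian expectation; K < 1 means less similarity among relatives than
Brownian motion predicts.  Kmult is the multivariate generalisation obtained
by summing the quadratic forms over trait columns (Euclidean geometry of the
shape tangent space); with one column it reduces exactly to K.  p-values come
from permuting trait rows across tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import Phylogeny

__all__ = ["SignalResult", "bm_simulate", "blomberg_k", "k_mult", "normalize_label"]


def normalize_label(label: str) -> str:
    """Documented tip/species matching normalization: trim, case-fold, underscores."""
    return str(label).strip().casefold().replace(" ", "_")


@dataclass
class SignalResult:
    statistic: float
    p: float
    n_permutations: int
    seed: int | None
    observed_ratio: float     # MSE0 / MSE
    expected_ratio: float     # the same ratio expected under BM
    kind: str = "K"


def _tree_matrices(tree: Phylogeny, labels: list[str]):
    order = {normalize_label(t): t for t in tree.tip_labels}
    mapped = []
    missing = []
    for lab in labels:
        key = normalize_label(lab)
        if key in order:
            mapped.append(order[key])
        else:
            missing.append(lab)
    if missing:
        raise ValueError(f"labels not found among tree tips: {missing}")
    C, _ = tree.vcv(order=mapped)
    return C


def bm_simulate(tree: Phylogeny, rate: float, dims: int = 1,
                seed: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Simulate zero-mean Brownian traits; returns (tips x dims values, labels).

    Tip covariance is rate x C with C the shared-path-length matrix; distinct
    dims are independent.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    C, labels = tree.vcv()
    n = len(labels)
    rng = np.random.default_rng(seed)
    if rate == 0 or np.allclose(C, 0):
        return np.zeros((n, dims)), labels
    # eigh-based square root: robust to the zero eigenvalues of star-like trees
    w, v = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, dims))
    return np.sqrt(rate) * (root @ z), labels


def _k_statistic(C: np.ndarray, Y: np.ndarray) -> tuple[float, float, float]:
    """Observed and expected MSE0/MSE ratios and their quotient (K)."""
    n = len(C)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    denom_a = ones @ Ci @ ones
    a = (ones @ Ci @ Y) / denom_a          # GLS phylogenetic mean, per column
    R = Y - a                              # residuals about it
    mse0 = float((R ** 2).sum()) / (n - 1)
    mse = float(np.einsum("id,ij,jd->", R, Ci, R)) / (n - 1)
    observed = mse0 / mse
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    return observed / expected, observed, expected


def blomberg_k(tree: Phylogeny, trait: dict[str, float] | np.ndarray,
               labels: list[str] | None = None, n_permutations: int = 1000,
               seed: int | None = None) -> SignalResult:
    """Univariate Blomberg K with a permutation test (trait shuffled across tips)."""
    if isinstance(trait, dict):
        labels = list(trait.keys())
        values = np.array([trait[k] for k in labels], dtype=float).reshape(-1, 1)
    else:
        values = np.asarray(trait, dtype=float).reshape(-1, 1)
        if labels is None:
            raise ValueError("labels required when trait is an array")
    res = k_mult(tree, values, labels, n_permutations=n_permutations, seed=seed)
    res.kind = "K"
    return res


def k_mult(tree: Phylogeny, shapes: np.ndarray, labels: list[str],
           n_permutations: int = 1000, seed: int | None = None) -> SignalResult:
    """Multivariate K on species scores (tips x axes); reduces to K for one axis."""
    Y = np.asarray(shapes, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if len(labels) != len(Y):
        raise ValueError("one label per row required")
    if len(Y) < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(Y.var(axis=0).sum(), 0):
        raise ValueError("constant trait: K undefined")
    C = _tree_matrices(tree, list(labels))
    k_obs, observed, expected = _k_statistic(C, Y)

    rng = np.random.default_rng(seed)
    exceed = 0
    n = len(Y)
    for _ in range(n_permutations):
        k_perm, _, _ = _k_statistic(C, Y[rng.permutation(n)])
        if k_perm >= k_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return SignalResult(statistic=float(k_obs), p=float(p),
                        n_permutations=n_permutations, seed=seed,
                        observed_ratio=float(observed),
                        expected_ratio=float(expected), kind="Kmult")
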