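"""Thin-plate-spline interpolation in 3D and its bending energy.

The 3D fundamental solution is linear in distance; we take the kernel as
U(r) = -r so that the bending-energy quadratic form is positive semidefinite
directly (the +r convention differs only by the overall sign of the kernel
block, and yields identical interpolants and identical energies).  For k
landmarks the full system is

    L [W | A]^T = [V | 0]^T,   L = [[K, P], [P^T, 0]],

with K_ij = U(|x_i - x_j|) and P = [1 | x].  The upper-left k x k block of
L^{-1} is the bending-energy matrix B: for a target V (k x 3),
energy = trace(V^T B V), which is zero exactly on affine maps.  Energies are
reported in this conventional (unnormalised) form, as in the morphometrics
literature; only ratios and minimisers ever matter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .landmark_io import LandmarkConfiguration

__all__ = [
    "TpsTransform",
    "fit_tps",
    "bending_energy_matrix",
    "bending_energy",
    "warp_points",
]

#: relative singularity threshold on the TPS system
_SINGULARITY_RTOL = 1e-12


class DegenerateConfigurationError(ValueError):
    """Coincident or otherwise degenerate source landmarks."""


def _points(x) -> np.ndarray:
    if isinstance(x, LandmarkConfiguration):
        return x.points
    return np.asarray(x, dtype=float)


def _kernel(r: np.ndarray) -> np.ndarray:
    return -r


@dataclass
class TpsTransform:
    """Exact TPS interpolant mapping ``source`` landmarks onto ``target``.

    ``affine`` is (4, 3): row 0 the translation, rows 1-3 the linear map;
    ``weights`` is (k, 3) and lies in the null space of the side conditions
    (columns sum to zero and are orthogonal to the source coordinates).
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray
    weights: np.ndarray

    def __call__(self, query) -> np.ndarray:
        return warp_points(self, query)

    def to_json(self) -> str:
        return json.dumps({
            "kernel": "U(r) = -r (3D)",
            "source": self.source.tolist(),
            "target": self.target.tolist(),
            "affine": self.affine.tolist(),
            "weights": self.weights.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "TpsTransform":
        d = json.loads(s)
        return cls(*(np.asarray(d[k], dtype=float)
                     for k in ("source", "target", "affine", "weights")))


def _build_system(source: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = len(source)
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
    K = _kernel(r)
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L, K


def _solve(L: np.ndarray, rhs: np.ndarray, context: str) -> np.ndarray:
    # LU with explicit conditioning check; configurations failing the
    # singularity threshold are rejected rather than regularised.
    try:
        lu, piv = scipy.linalg.lu_factor(L)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateConfigurationError(f"{context}: singular TPS system") from exc
    diag = np.abs(np.diag(lu))
    if diag.min() < _SINGULARITY_RTOL * diag.max():
        raise DegenerateConfigurationError(
            f"{context}: TPS system numerically singular "
            f"(relative pivot {diag.min() / diag.max():.2e})"
        )
    return scipy.linalg.lu_solve((lu, piv), rhs)


def fit_tps(source, target) -> TpsTransform:
    """Fit the exact 3D TPS interpolant taking source landmarks to target."""
    src, tgt = _points(source), _points(target)
    if src.shape != tgt.shape:
        raise ValueError(f"point-count mismatch: {src.shape} vs {tgt.shape}")
    k = len(src)
    if k < 4:
        raise ValueError("TPS in 3D needs at least 4 landmarks")
    L, _ = _build_system(src)
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    sol = _solve(L, rhs, "fit_tps")
    return TpsTransform(src.copy(), tgt.copy(), affine=sol[k:], weights=sol[:k])


def warp_points(transform: TpsTransform, query) -> np.ndarray:
    """Evaluate the fitted warp at arbitrary 3D points."""
    q = np.atleast_2d(_points(query))
    r = np.linalg.norm(q[:, None, :] - transform.source[None, :, :], axis=2)
    return (_kernel(r) @ transform.weights
            + transform.affine[0]
            + q @ transform.affine[1:])


def bending_energy_matrix(reference) -> np.ndarray:
    """The k x k PSD matrix B with energy = trace(D^T B D) for displacements D.

    B annihilates affine displacement fields: its null space contains the
    constant vector and the three coordinate columns of the reference.
    """
    ref = _points(reference)
    k = len(ref)
    L, _ = _build_system(ref)
    inv = _solve(L, np.eye(k + 4), "bending_energy_matrix")
    B = inv[:k, :k]
    B = 0.5 * (B + B.T)  # symmetrise away factorization noise
    return B


def bending_energy(source, target) -> float:
    """TPS bending energy of the source -> target map (0 iff affine)."""
    src, tgt = _points(source), _points(target)
    B = bending_energy_matrix(src)
    e = float(np.einsum("id,ij,jd->", tgt, B, tgt))
    return max(e, 0.0)


def bending_energy_from_transform(t: TpsTransform) -> float:
    """Independent route: energy = trace(W^T K W) from the fitted weights."""
    r = np.linalg.norm(t.source[:, None, :] - t.source[None, :, :], axis=2)
    return float(np.einsum("id,ij,jd->", t.weights, _kernel(r), t.weights))
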