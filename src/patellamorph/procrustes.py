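"""Superimposition: centroid size, mirroring, GPA and Procrustes distances.

Scaling removes size by dividing each configuration by its centroid size; the
sizes themselves are carried alongside the aligned coordinates because all
downstream allometry regresses shape on log CS.  Rotations are always proper:
chirality is never absorbed by the fit — left bones are reflected explicitly
with :func:`mirror` beforehand, mimicking how left patellae were mirrored
before digitisation in the source protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, ShapeSample

log = logging.getLogger(__name__)

__all__ = [
    "AlignedSample",
    "centroid_size",
    "mirror",
    "gpa",
    "procrustes_distance",
    "species_mean_shapes",
    "optimal_rotation",
]

_CONV_TOL = 1e-10
_MAX_ITER = 100


def _points(x) -> np.ndarray:
    if isinstance(x, LandmarkConfiguration):
        return x.points
    return np.asarray(x, dtype=float)


def centroid_size(config) -> float:
    """sqrt of summed squared distances of the landmarks to their centroid."""
    pts = _points(config)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs <= 0.0:
        raise ValueError("all landmarks coincide: centroid size is zero")
    return cs


def mirror(config: LandmarkConfiguration, axis: int = 1) -> LandmarkConfiguration:
    """Sagittal flip: negate one coordinate (default y) and toggle the side label."""
    pts = config.points.copy()
    pts[:, axis] = -pts[:, axis]
    toggled = {"left": "right", "right": "left"}.get(config.side, "unknown")
    out = config.with_points(pts)
    out.side = toggled
    return out


def optimal_rotation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||moving @ R - fixed|| (Kabsch)."""
    u, _, vt = np.linalg.svd(moving.T @ fixed)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(len(u))
    s[-1] = d
    return (u * s) @ vt


@dataclass
class AlignedSample:
    """GPA output: unit-size, centred, rotated configurations and their sizes."""

    sample: ShapeSample
    aligned: np.ndarray                    # (n, k, 3)
    consensus: np.ndarray                  # (k, 3) mean of aligned
    centroid_sizes: np.ndarray             # (n,)
    iterations_run: int = 0
    converged: bool = True
    scaled: bool = True

    @property
    def n(self) -> int:
        return len(self.aligned)

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def specimen_ids(self) -> list[str]:
        return self.sample.specimen_ids

    def flattened(self) -> np.ndarray:
        """(n, 3k) row-per-specimen view of the aligned coordinates."""
        return self.aligned.reshape(self.n, -1)

    def consensus_configuration(self) -> LandmarkConfiguration:
        c0 = self.sample.configurations[0]
        return LandmarkConfiguration("consensus", self.consensus,
                                     c0.classes, c0.curve_ids)

    def aligned_configurations(self) -> list[LandmarkConfiguration]:
        return [c.with_points(p) for c, p in zip(self.sample.configurations, self.aligned)]

    def sizes_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "specimen": self.specimen_ids,
            "centroid_size": self.centroid_sizes,
            "log_centroid_size": np.log(self.centroid_sizes),
        })


def gpa(sample: ShapeSample | list[LandmarkConfiguration], scale: bool = True) -> AlignedSample:
    """Generalized Procrustes analysis.

    Iteratively centres, (optionally) scales to unit centroid size and rotates
    every configuration onto the running consensus until the consensus moves
    by less than 1e-10 RMS or 100 iterations.  The returned consensus is the
    plain mean of the aligned configurations.
    """
    if not isinstance(sample, ShapeSample):
        sample = ShapeSample(list(sample))
    n = len(sample)
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    X = sample.as_array().copy()
    sizes = np.empty(n)
    for i, config in enumerate(sample.configurations):
        X[i] -= X[i].mean(axis=0)
        try:
            sizes[i] = centroid_size(X[i])
        except ValueError as exc:
            raise ValueError(f"degenerate configuration {config.specimen_id}") from exc
        if scale:
            X[i] /= sizes[i]

    consensus = X[0].copy()
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < _CONV_TOL:
            converged = True
            break
    if not converged:
        log.warning("GPA did not converge in %d iterations", _MAX_ITER)
    # final pass so every configuration is optimally rotated to the reported mean
    for i in range(n):
        X[i] = X[i] @ optimal_rotation(X[i], consensus)
    consensus = X.mean(axis=0)
    return AlignedSample(sample, X, consensus, sizes,
                         iterations_run=it, converged=converged, scaled=scale)


def total_procrustes_ss(aligned: AlignedSample) -> float:
    """Sum of squared deviations of aligned configurations about the consensus."""
    return float(((aligned.aligned - aligned.consensus) ** 2).sum())


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance: RMS residual after centring, unit scaling
    and optimal proper rotation."""
    pa, pb = _points(a).copy(), _points(b).copy()
    if pa.shape != pb.shape:
        raise ValueError("configurations must share one scheme")
    pa -= pa.mean(axis=0)
    pb -= pb.mean(axis=0)
    pa /= centroid_size(pa)
    pb /= centroid_size(pb)
    pa = pa @ optimal_rotation(pa, pb)
    return float(np.sqrt(((pa - pb) ** 2).sum()))


def species_mean_shapes(aligned: AlignedSample, species: list[str]) -> ShapeSample:
    """Per-species Procrustes consensus from the first GPA's aligned coordinates.

    The output feeds the two-step protocol: superimpose these means in a second
    GPA before ordination or phylogenetic-signal tests.
    """
    if len(species) != aligned.n:
        raise ValueError("one species label per specimen required")
    c0 = aligned.sample.configurations[0]
    seen: dict[str, list[int]] = {}
    for i, s in enumerate(species):
        seen.setdefault(str(s), []).append(i)
    configs = []
    for name, idx in seen.items():
        if not idx:
            raise ValueError(f"species {name!r} has no specimens")
        mean = aligned.aligned[idx].mean(axis=0)
        configs.append(LandmarkConfiguration(name, mean, c0.classes, c0.curve_ids))
    return ShapeSample(configs, provenance={"kind": "species mean shapes"})
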