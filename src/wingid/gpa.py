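"""Generalized Procrustes superimposition, centroid size, and repeatability.

Shape is what remains of a landmark configuration after translation, scale
and rotation are removed.  The superimposition used here is the partial
Procrustes fit: every configuration is centred, scaled to unit centroid
size, and rotated (rotation only — reflections are never allowed, since all
wings are prepared from the same side) onto an iteratively updated
consensus.  Aligned shapes are finally projected into the tangent space
orthogonal to the consensus, where ordinary multivariate statistics apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .containers import LandmarkConfiguration, MorphoDataset

__all__ = [
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "repeatability",
    "AlignedShapes",
    "RepeatabilityResult",
]

#: Convergence tolerance on the RMS change of the consensus between iterations.
GPA_TOL = 1e-8
#: Iteration cap; non-convergence is flagged on the result, not raised.
GPA_MAX_ITER = 100


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.landmarks
    x = np.asarray(config, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected a (k, 2) coordinate array, got {x.shape}")
    return x


def centroid_size(config) -> float:
    """Centroid size: root summed squared landmark distances to the centroid.

    Translation- and rotation-invariant, and homogeneous of degree one in
    the coordinates (scaling the configuration by c scales CS by c).
    """
    x = _as_coords(config)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    centred = x - x.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def _centre_scale(x: np.ndarray) -> np.ndarray:
    centred = x - x.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centred / cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||x R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """Output of generalized Procrustes analysis.

    consensus        -- mean shape, (k, 2), centred, unit centroid size
    procrustes_coords-- (n, 2k) aligned unit-size coordinates
    tangent_coords   -- (n, 2k) coordinates projected orthogonal to the consensus
    centroid_sizes   -- original sizes (mm) recorded before scaling
    """

    consensus: np.ndarray
    procrustes_coords: np.ndarray
    tangent_coords: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    specimen_ids: Optional[np.ndarray] = None
    species_labels: Optional[np.ndarray] = None
    replicates: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]


def gpa(
    dataset: Union[MorphoDataset, Sequence, np.ndarray],
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> AlignedShapes:
    """Iterative generalized Procrustes superimposition.

    Each configuration is centred and scaled to unit centroid size, then
    repeatedly rotated onto the running consensus; the consensus is the
    re-normalised mean of the rotated shapes.  Iteration stops when the
    consensus RMS change drops below ``tol``.  Aligned shapes are finally
    projected into the Kendall tangent space at the consensus (component
    along the consensus removed), which makes the tangent coordinates sum
    to zero across specimens exactly.
    """
    if isinstance(dataset, MorphoDataset):
        coords = dataset.coords()
        ids, labels, reps = (
            dataset.specimen_ids,
            dataset.species_labels,
            dataset.replicates,
        )
    else:
        coords = np.stack([_as_coords(c) for c in np.asarray(dataset, dtype=float)])
        ids = labels = reps = None
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("GPA requires at least two configurations")
    if k < 3:
        raise ValueError("GPA requires at least three landmarks")

    sizes = np.array([centroid_size(c) for c in coords])
    unit = np.stack([_centre_scale(c) for c in coords])

    consensus = _centre_scale(unit[0])
    aligned = unit.copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
        new_consensus = _centre_scale(aligned.mean(axis=0))
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    # Final pass so every shape is rotated onto the converged consensus.
    for i in range(n):
        aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
    # Consensus as the normalised mean of the final alignment: the tangent
    # projection below then zeroes the column means exactly.
    consensus = _centre_scale(aligned.mean(axis=0))

    flat = aligned.reshape(n, 2 * k)
    c = consensus.reshape(2 * k)
    tangent = flat - np.outer(flat @ c, c)

    return AlignedShapes(
        consensus=consensus,
        procrustes_coords=flat,
        tangent_coords=tangent,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
        species_labels=labels,
        replicates=reps,
    )


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Root sum of squared differences after both shapes are centred, scaled
    to unit centroid size, and optimally rotated (no reflection).  Zero iff
    the shapes are identical up to translation, scale and rotation.
    """
    xa, xb = _as_coords(a), _as_coords(b)
    if xa.shape != xb.shape:
        raise ValueError(f"landmark count mismatch: {xa.shape[0]} vs {xb.shape[0]}")
    ua, ub = _centre_scale(xa), _centre_scale(xb)
    rot = ua @ _optimal_rotation(ua, ub)
    return float(np.sqrt(((rot - ub) ** 2).sum()))


@dataclass
class RepeatabilityResult:
    """Procrustes-ANOVA repeatability of landmark digitization.

    R = var_among / (var_among + var_within): the proportion of total shape
    variance attributable to real among-individual differences rather than
    digitizing error.  measurement_error = 1 - R.
    """

    R: float
    measurement_error: float
    variance_among: float
    variance_within: float
    n_individuals: int
    n_replicates: int
    ss_among: float
    ss_within: float
    ss_total: float


def repeatability(dataset: MorphoDataset) -> RepeatabilityResult:
    """Two-level Procrustes ANOVA on jointly superimposed replicate digitizations.

    All digitizations enter one GPA; tangent coordinates are then
    partitioned into among-individual and within-individual (replicate)
    sums of squares, summed over coordinates.  Variance components follow
    the expected mean squares: var_within = MS_within and
    var_among = (MS_among - MS_within) / r0, floored at zero, where r0 is
    the effective replicate number (equal to r for balanced designs).
    """
    by_specimen: dict[str, list[int]] = {}
    for i, cfg in enumerate(dataset):
        by_specimen.setdefault(cfg.specimen_id, []).append(i)
    short = sorted(s for s, idx in by_specimen.items() if len(idx) < 2)
    if short:
        raise ValueError(
            f"specimens with fewer than 2 replicates: {short}"
        )

    aligned = gpa(dataset)
    t = aligned.tangent_coords
    grand = t.mean(axis=0)

    n_ind = len(by_specimen)
    n_total = len(dataset)
    counts = np.array([len(idx) for idx in by_specimen.values()], dtype=float)
    ss_among = 0.0
    ss_within = 0.0
    for idx in by_specimen.values():
        grp = t[idx]
        m = grp.mean(axis=0)
        ss_among += len(idx) * float(((m - grand) ** 2).sum())
        ss_within += float(((grp - m) ** 2).sum())
    ss_total = float(((t - grand) ** 2).sum())

    df_among = n_ind - 1
    df_within = n_total - n_ind
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    # Effective replicate number (Sokal & Rohlf n0); equals r when balanced.
    r0 = (n_total - (counts**2).sum() / n_total) / df_among
    var_within = ms_within
    var_among = max(0.0, (ms_among - ms_within) / r0)
    total = var_among + var_within
    r_index = 1.0 if total == 0.0 else var_among / total

    return RepeatabilityResult(
        R=r_index,
        measurement_error=1.0 - r_index,
        variance_among=var_among,
        variance_within=var_within,
        n_individuals=n_ind,
        n_replicates=int(round(counts.mean())),
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
    )
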