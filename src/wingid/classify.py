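"""Leave-one-out (jackknife) validated classification by wing size and shape.

Each specimen is removed in turn, the classifier is refitted on the rest,
and the specimen is assigned: for size, to the species whose leave-one-out
normal density (species-specific mean and SD) is highest at the specimen's
centroid size; for shape, to the species with the smallest Mahalanobis
distance computed from leave-one-out group means and pooled within-group
covariance.  Superimposition is performed once on the full sample — one
specimen's influence on the consensus is negligible — so only the
statistical model is refitted per fold.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .containers import ConfusionMatrix, MorphoDataset
from .gpa import AlignedShapes, centroid_size
from .shapestats import ShapeVariables, _solve_spd, pooled_within_covariance

__all__ = ["jackknife_size", "jackknife_shape"]


def jackknife_size(
    dataset: Union[MorphoDataset, np.ndarray],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Jackknifed maximum-likelihood classification on centroid size.

    Species CS distributions are modelled as univariate normals with
    species-specific variances.  Ties in density go to the first species in
    canonical label order.
    """
    if isinstance(dataset, MorphoDataset):
        sizes = np.array([centroid_size(c) for c in dataset])
        labels = dataset.species_labels
    else:
        sizes = np.asarray(dataset, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a size array")
        labels = np.asarray(labels)
    species = list(dict.fromkeys(labels))
    for s in species:
        if (labels == s).sum() < 3:
            raise ValueError(f"species {s!r} has fewer than 3 specimens")

    predicted = []
    for i in range(sizes.size):
        keep = np.ones(sizes.size, dtype=bool)
        keep[i] = False
        best_s, best_ll = None, -np.inf
        for s in species:
            v = sizes[keep & (labels == s)]
            mu, sd = v.mean(), v.std(ddof=1)
            if sd == 0.0:
                # Degenerate fit: infinite density exactly at mu, else zero.
                ll = np.inf if sizes[i] == mu else -np.inf
            else:
                ll = -np.log(sd) - 0.5 * ((sizes[i] - mu) / sd) ** 2
            if ll > best_ll:
                best_s, best_ll = s, ll
        predicted.append(best_s)
    return ConfusionMatrix.from_assignments(labels, predicted, species)


def jackknife_shape(
    aligned_or_scores: Union[AlignedShapes, ShapeVariables, np.ndarray],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Jackknifed nearest-group Mahalanobis classification on shape variables.

    Group means and the pooled within-group covariance are recomputed for
    every fold without the held-out specimen.  Distance ties go to the
    first species in canonical label order (strict inequality required to
    displace the incumbent).
    """
    if isinstance(aligned_or_scores, AlignedShapes):
        from .shapestats import shape_pca

        if labels is None:
            labels = aligned_or_scores.species_labels
        x = shape_pca(aligned_or_scores).scores
    elif isinstance(aligned_or_scores, ShapeVariables):
        x = aligned_or_scores.scores
    else:
        x = np.asarray(aligned_or_scores, dtype=float)
    if labels is None:
        raise ValueError("species labels required")
    labels = np.asarray(labels)
    n, d = x.shape
    species = list(dict.fromkeys(labels))
    g = len(species)
    if n - g - 1 < d:
        raise ValueError(
            f"leave-one-out pooled dof n - g - 1 = {n - g - 1} < d = {d}"
        )

    predicted = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        s_cov, means, _ = pooled_within_covariance(x[keep], labels[keep])
        solve = _solve_spd(s_cov)
        best_s, best_d2 = None, np.inf
        for s in species:
            delta = x[i] - means[s]
            d2 = float(delta @ solve(delta))
            if d2 < best_d2:
                best_s, best_d2 = s, d2
        predicted.append(best_s)
    return ConfusionMatrix.from_assignments(labels, predicted, species)
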