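"""Shape variables, allometry, size ANOVA, Mahalanobis distances, CVA, UPGMA.

Shape variables are principal-component scores of the tangent coordinates.
Every downstream statistic used here (Mahalanobis D, canonical variates,
jackknife classification) is exactly invariant to replacing those scores by
any other full-rank linear transform of the tangent coordinates, so this
choice is statistically equivalent to thin-plate-spline partial-warp scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.stats

from .containers import MorphoDataset, PairwiseDistanceMatrix, PermutationTestResult
from .gpa import AlignedShapes, centroid_size

__all__ = [
    "shape_pca",
    "allometry_test",
    "size_permutation_anova",
    "mahalanobis_matrix",
    "mahalanobis_permutation_tests",
    "discriminant_map",
    "upgma",
    "ShapeVariables",
    "AllometryResult",
    "SizeAnovaResult",
    "CanonicalVariates",
]


# ---------------------------------------------------------------------------
# principal components of shape


@dataclass
class ShapeVariables:
    scores: np.ndarray  # (n, d), centred
    loadings: np.ndarray  # (2k, d), orthonormal columns
    eigenvalues: np.ndarray  # (d,), descending
    percent_variance: np.ndarray  # (d,)


def shape_pca(aligned: AlignedShapes, rel_tol: float = 1e-9) -> ShapeVariables:
    """PCA of tangent coordinates; retains components with non-negligible variance.

    For k 2-D landmarks the tangent space has dimension 2k - 4 (translation,
    scale and rotation removed), so at most 2k - 4 components survive.
    Component signs follow the convention that the largest-magnitude loading
    of each component is positive.
    """
    t = aligned.tangent_coords
    n = t.shape[0]
    if n <= 2:
        raise ValueError("PCA requires more than two specimens")
    centred = t - t.mean(axis=0)
    cov = centred.T @ centred / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > max(eigval[0], 0.0) * rel_tol
    keep &= eigval > 0
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1.0
    scores = centred @ eigvec
    pct = 100.0 * eigval / eigval.sum()
    return ShapeVariables(
        scores=scores, loadings=eigvec, eigenvalues=eigval, percent_variance=pct
    )


# ---------------------------------------------------------------------------
# allometry


@dataclass
class AllometryResult:
    """Regression of the first shape principal component on centroid size."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def allometry_test(
    aligned: AlignedShapes,
    n_permutations: int = 1000,
    seed: int = 0,
    shape_vars: Optional[ShapeVariables] = None,
) -> AllometryResult:
    """Size–shape covariation: OLS of PC1 on CS with a permutation p-value.

    The null distribution is generated by permuting centroid sizes against
    the fixed PC1 scores and recomputing R²; p carries the +1 correction.
    """
    cs = np.asarray(aligned.centroid_sizes, dtype=float)
    if cs.size < 3:
        raise ValueError("allometry test requires at least 3 specimens")
    if np.var(cs) == 0:
        raise ValueError("centroid size has zero variance")
    if shape_vars is None:
        shape_vars = shape_pca(aligned)
    pc1 = shape_vars.scores[:, 0]

    fit = scipy.stats.linregress(cs, pc1)
    r2_obs = fit.rvalue**2

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cs)
        r = np.corrcoef(perm, pc1)[0, 1]
        if r * r >= r2_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AllometryResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# wing size: permutation ANOVA with compact letter display


@dataclass
class SizeAnovaResult:
    overall: PermutationTestResult
    pairwise: dict
    letters: dict
    species: list
    means: np.ndarray
    sds: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    ns: np.ndarray


def _f_statistic(values: np.ndarray, codes: np.ndarray, g: int) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for grp in range(g):
        v = values[codes == grp]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b, df_w = g - 1, values.size - g
    if ss_within == 0:
        return np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def _maximal_cliques(nodes: list, adjacency: dict) -> list:
    cliques = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            bron_kerbosch(r | {v}, p & adjacency[v], x & adjacency[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(nodes), set())
    return cliques


def compact_letter_display(
    species: Sequence[str], means: Sequence[float], not_different: set
) -> dict:
    """Assign letters so species sharing one are not significantly different.

    One letter per maximal clique of the "not significantly different"
    graph, ordered by the smallest group mean in the clique.
    """
    idx = {s: i for i, s in enumerate(species)}
    order = {s: r for r, s in enumerate(sorted(species, key=lambda s: means[idx[s]]))}
    adjacency = {s: {t for t in species if frozenset((s, t)) in not_different} for s in species}
    cliques = _maximal_cliques(list(species), adjacency)
    cliques.sort(key=lambda c: min(order[s] for s in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {s: "" for s in species}
    for i, clique in enumerate(cliques):
        for s in sorted(clique, key=order.get):
            letters[s] += alphabet[i % len(alphabet)]
    return letters


def size_permutation_anova(
    dataset: Union[MorphoDataset, np.ndarray],
    labels: Optional[Sequence[str]] = None,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SizeAnovaResult:
    """Permutation one-way ANOVA of centroid size across species.

    The overall test permutes species labels against sizes and compares the
    F statistic; each pairwise test permutes the pooled pair's sizes and
    compares |mean difference|, Bonferroni-adjusted over all g(g-1)/2
    pairs.  Species sharing a compact-display letter are those whose
    adjusted pairwise p exceeds ``alpha``.
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
    g = len(species)
    if g < 2:
        raise ValueError("at least two species required")
    codes = np.array([species.index(l) for l in labels])
    for s in species:
        if (labels == s).sum() < 2:
            raise ValueError(f"species {s!r} has fewer than 2 specimens")

    rng = np.random.default_rng(seed)
    f_obs = _f_statistic(sizes, codes, g)
    hits = 0
    for _ in range(n_permutations):
        if _f_statistic(sizes, rng.permutation(codes), g) >= f_obs:
            hits += 1
    p_overall = (hits + 1) / (n_permutations + 1)
    overall = PermutationTestResult(
        observed=float(f_obs),
        p_raw=p_overall,
        p_adjusted=p_overall,
        n_permutations=n_permutations,
        seed=seed,
    )

    n_pairs = g * (g - 1) // 2
    pairwise: dict = {}
    not_different: set = set()
    for a, b in combinations(species, 2):
        va, vb = sizes[labels == a], sizes[labels == b]
        obs = abs(va.mean() - vb.mean())
        pooled = np.concatenate([va, vb])
        na = va.size
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if abs(perm[:na].mean() - perm[na:].mean()) >= obs:
                hits += 1
        p_raw = (hits + 1) / (n_permutations + 1)
        p_adj = min(1.0, p_raw * n_pairs)
        pairwise[(a, b)] = PermutationTestResult(
            observed=float(obs),
            p_raw=p_raw,
            p_adjusted=p_adj,
            n_permutations=n_permutations,
            seed=seed,
        )
        if p_adj > alpha:
            not_different.add(frozenset((a, b)))

    means = np.array([sizes[labels == s].mean() for s in species])
    letters = compact_letter_display(species, means, not_different)
    return SizeAnovaResult(
        overall=overall,
        pairwise=pairwise,
        letters=letters,
        species=species,
        means=means,
        sds=np.array([sizes[labels == s].std(ddof=1) for s in species]),
        mins=np.array([sizes[labels == s].min() for s in species]),
        maxs=np.array([sizes[labels == s].max() for s in species]),
        ns=np.array([(labels == s).sum() for s in species]),
    )


# ---------------------------------------------------------------------------
# Mahalanobis machinery


def pooled_within_covariance(
    x: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, dict, list]:
    """Pooled within-group covariance with n - g denominator, plus group means."""
    species = list(dict.fromkeys(labels))
    n, d = x.shape
    g = len(species)
    scatter = np.zeros((d, d))
    means = {}
    for s in species:
        grp = x[labels == s]
        m = grp.mean(axis=0)
        means[s] = m
        dev = grp - m
        scatter += dev.T @ dev
    return scatter / (n - g), means, species


def _solve_spd(s: np.ndarray, metric: str = "covariance"):
    """Cholesky solve against S, falling back to ridge shrinkage if singular."""
    try:
        factor = scipy.linalg.cho_factor(s)
    except scipy.linalg.LinAlgError:
        lam = 1e-8 * np.trace(s) / s.shape[0]
        if lam <= 0:
            raise ValueError(
                f"singular pooled {metric}: reduce dimensions or add data"
            )
        warnings.warn(
            f"pooled {metric} numerically singular; applying ridge shrinkage "
            f"lambda={lam:.3g}",
            stacklevel=2,
        )
        factor = scipy.linalg.cho_factor(s + lam * np.eye(s.shape[0]))
    return lambda b: scipy.linalg.cho_solve(factor, b)


def _mahalanobis_d(x: np.ndarray, labels: np.ndarray) -> float:
    """Mahalanobis distance between exactly two groups, pair-pooled covariance."""
    s, means, species = pooled_within_covariance(x, labels)
    delta = means[species[0]] - means[species[1]]
    solve = _solve_spd(s)
    return float(np.sqrt(delta @ solve(delta)))


def mahalanobis_matrix(
    shape_vars: Union[ShapeVariables, np.ndarray], labels: Sequence[str]
) -> PairwiseDistanceMatrix:
    """Pairwise Mahalanobis distances between species mean shapes.

    D_ij = sqrt((m_i - m_j)' S^-1 (m_i - m_j)) with S the within-group
    covariance pooled over *all* groups.  Invariant to any nonsingular
    linear transform of the shape variables.
    """
    x = shape_vars.scores if isinstance(shape_vars, ShapeVariables) else np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    n, d = x.shape
    g = len(set(labels.tolist()))
    if n - g < d:
        raise ValueError(
            f"pooled degrees of freedom n - g = {n - g} < dimension d = {d}; "
            "reduce dimensions"
        )
    s, means, species = pooled_within_covariance(x, labels)
    solve = _solve_spd(s)
    values = np.zeros((g, g))
    for i, j in combinations(range(g), 2):
        delta = means[species[i]] - means[species[j]]
        values[i, j] = values[j, i] = np.sqrt(delta @ solve(delta))
    return PairwiseDistanceMatrix(
        labels=list(species), values=values, metric_name="mahalanobis"
    )


def mahalanobis_permutation_tests(
    shape_vars: Union[ShapeVariables, np.ndarray],
    labels: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Pairwise permutation tests of the Mahalanobis distance.

    For each species pair, labels are permuted within the pair and D is
    recomputed from the pair-pooled covariance; p = (#{D_perm >= D_obs} + 1)
    / (N + 1), Bonferroni-adjusted over g(g-1)/2 pairs.
    """
    x = shape_vars.scores if isinstance(shape_vars, ShapeVariables) else np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    species = list(dict.fromkeys(labels))
    n_pairs = len(species) * (len(species) - 1) // 2
    rng = np.random.default_rng(seed)
    results: dict = {}
    for a, b in combinations(species, 2):
        mask = (labels == a) | (labels == b)
        sub = x[mask]
        sub_labels = labels[mask]
        obs = _mahalanobis_d(sub, sub_labels)
        hits = 0
        for _ in range(n_permutations):
            if _mahalanobis_d(sub, rng.permutation(sub_labels)) >= obs:
                hits += 1
        p_raw = (hits + 1) / (n_permutations + 1)
        results[(a, b)] = PermutationTestResult(
            observed=obs,
            p_raw=p_raw,
            p_adjusted=min(1.0, p_raw * n_pairs),
            n_permutations=n_permutations,
            seed=seed,
        )
    return results


# ---------------------------------------------------------------------------
# canonical variates (discriminant factor map)


@dataclass
class CanonicalVariates:
    """Canonical variate (discriminant) axes for the species factor map.

    Axes are scaled so the pooled within-group variance along each axis is
    one; for two groups the separation of the group means on axis 1 then
    equals their Mahalanobis distance.
    """

    axes: np.ndarray  # (d, m) canonical vectors
    scores: np.ndarray  # (n, m)
    group_means: dict  # species -> (m,) axis means
    eigenvalues: np.ndarray  # (m,) descending
    species: list


def discriminant_map(
    shape_vars: Union[ShapeVariables, np.ndarray],
    labels: Sequence[str],
    n_components: Optional[int] = None,
) -> CanonicalVariates:
    """Canonical variate analysis of shape variables across species."""
    x = shape_vars.scores if isinstance(shape_vars, ShapeVariables) else np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    n, d = x.shape
    sw, means, species = pooled_within_covariance(x, labels)
    g = len(species)
    if g < 2:
        raise ValueError("at least two groups required")
    if n - g < d:
        raise ValueError("pooled degrees of freedom too small for dimension")
    grand = x.mean(axis=0)
    sb = np.zeros((d, d))
    for s in species:
        dev = means[s] - grand
        sb += (labels == s).sum() * np.outer(dev, dev)
    sb /= n - 1

    try:
        eigval, eigvec = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError:
        lam = 1e-8 * np.trace(sw) / d
        warnings.warn(
            f"within-group covariance singular; ridge shrinkage lambda={lam:.3g}",
            stacklevel=2,
        )
        eigval, eigvec = scipy.linalg.eigh(sb, sw + lam * np.eye(d))
    order = np.argsort(eigval)[::-1]
    m = min(g - 1, d) if n_components is None else min(n_components, g - 1, d)
    eigval, eigvec = eigval[order[:m]], eigvec[:, order[:m]]
    # scipy normalises generalized eigenvectors to v' Sw v = 1 already;
    # re-normalise defensively for numerical drift.
    norms = np.sqrt(np.einsum("ij,jk,ki->i", eigvec.T, sw, eigvec))
    eigvec = eigvec / norms
    scores = (x - grand) @ eigvec
    group_means = {s: scores[labels == s].mean(axis=0) for s in species}
    return CanonicalVariates(
        axes=eigvec,
        scores=scores,
        group_means=group_means,
        eigenvalues=np.clip(eigval, 0, None),
        species=species,
    )


# ---------------------------------------------------------------------------
# UPGMA phenogram


def upgma(dist: PairwiseDistanceMatrix) -> str:
    """UPGMA (average-linkage) phenogram as a Newick string.

    Ultrametric: every merge happens at height = distance / 2, branch
    lengths are height differences.  Tied merges are broken by the
    lexicographically smallest pair of member-label tuples, so output is
    deterministic.
    """
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    # cluster state: id -> (sorted member tuple, size, height, newick)
    clusters = {
        i: ((lab,), 1, 0.0, lab) for i, lab in enumerate(labels)
    }
    d = {
        frozenset((i, j)): float(dist.values[i, j])
        for i, j in combinations(range(len(labels)), 2)
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(clusters[c][0] for c in kv[0])),
            ),
        )
        (pair, dmin) = best
        i, j = sorted(pair, key=lambda c: clusters[c][0])
        mi, ni, hi, si = clusters[i]
        mj, nj, hj, sj = clusters[j]
        height = dmin / 2.0
        newick = f"({si}:{height - hi:.10g},{sj}:{height - hj:.10g})"
        members = tuple(sorted(mi + mj))
        for other in clusters:
            if other in (i, j):
                continue
            dio = d.pop(frozenset((i, other)))
            djo = d.pop(frozenset((j, other)))
            d[frozenset((next_id, other))] = (ni * dio + nj * djo) / (ni + nj)
        del d[pair]
        del clusters[i], clusters[j]
        clusters[next_id] = (members, ni + nj, height, newick)
        next_id += 1
    (_, _, _, newick) = next(iter(clusters.values()))
    return newick + ";"
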