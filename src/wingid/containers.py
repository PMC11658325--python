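"""Core data containers shared across the morphometric and barcode tracks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 2-D wing landmarks.

    Coordinates are in millimetres when the source data carried a scale
    factor; landmark order is anatomically meaningful and preserved.
    """

    specimen_id: str
    species: str
    landmarks: np.ndarray  # (k, 2) float array
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise ValueError(
                f"landmarks must be a (k, 2) array, got shape {lm.shape}"
            )
        if not np.all(np.isfinite(lm)):
            raise ValueError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )
        object.__setattr__(self, "landmarks", lm)

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]

    def key(self) -> tuple:
        return (self.specimen_id, self.replicate)


class MorphoDataset:
    """A validated collection of landmark configurations.

    All configurations must share the same landmark count k, and the
    (specimen_id, replicate) pair must be unique within the dataset.
    """

    def __init__(self, configurations: Sequence[LandmarkConfiguration]):
        configs = list(configurations)
        if not configs:
            raise ValueError("dataset must contain at least one configuration")
        k = configs[0].k
        for c in configs:
            if c.k != k:
                raise ValueError(
                    f"inconsistent landmark count: specimen {c.specimen_id!r} "
                    f"has {c.k} landmarks, expected {k}"
                )
        keys = [c.key() for c in configs]
        if len(set(keys)) != len(keys):
            dup = sorted({key for key in keys if keys.count(key) > 1})
            raise ValueError(f"duplicate (specimen_id, replicate) keys: {dup}")
        self.configurations = configs
        self.k = k

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.configurations:
            seen.setdefault(c.species, None)
        return list(seen)

    @property
    def species_labels(self) -> np.ndarray:
        return np.array([c.species for c in self.configurations])

    @property
    def specimen_ids(self) -> np.ndarray:
        return np.array([c.specimen_id for c in self.configurations])

    @property
    def replicates(self) -> np.ndarray:
        return np.array(
            [-1 if c.replicate is None else c.replicate for c in self.configurations]
        )

    def coords(self) -> np.ndarray:
        """Stacked raw coordinates, shape (n, k, 2)."""
        return np.stack([c.landmarks for c in self.configurations])

    def subset(self, indices: Iterable[int]) -> "MorphoDataset":
        return MorphoDataset([self.configurations[i] for i in indices])


@dataclass
class PairwiseDistanceMatrix:
    """Labelled symmetric distance matrix (Mahalanobis, K2P, ...).

    NaN entries are tolerated (they mark undefined pairwise distances,
    e.g. saturated K2P comparisons); consumers that cannot handle them
    must check :attr:`n_undefined`.
    """

    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = len(self.labels)
        if v.shape != (g, g):
            raise ValueError(f"matrix shape {v.shape} does not match {g} labels")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValueError("matrix must be symmetric")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n_undefined(self) -> int:
        off = ~np.eye(len(self.labels), dtype=bool)
        return int(np.isnan(self.values[off]).sum() // 2)

    def __getitem__(self, pair: tuple) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ConfusionMatrix:
    """Jackknife assignment counts: rows = observed species, columns = predicted."""

    labels: list[str]
    counts: np.ndarray  # (g, g) ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        g = len(self.labels)
        if c.shape != (g, g):
            raise ValueError("counts shape does not match labels")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    @classmethod
    def from_assignments(
        cls, observed: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        labels = list(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for o, p in zip(observed, predicted, strict=True):
            counts[idx[o], idx[p]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        sizes = self.class_sizes
        with np.errstate(invalid="ignore"):
            return np.where(sizes > 0, np.diag(self.counts) / sizes, np.nan)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class PermutationTestResult:
    """A permutation test with the +1 finite-sample correction.

    p_raw = (#{stat_perm >= stat_obs} + 1) / (n_permutations + 1), so p is
    always in (0, 1]; p_adjusted is the Bonferroni-corrected value.
    """

    observed: float
    p_raw: float
    p_adjusted: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError("p_raw must be in (0, 1]")
        if not (0.0 < self.p_adjusted <= 1.0):
            raise ValueError("p_adjusted must be in (0, 1]")
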