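"""COI barcode evaluation: K2P distances, haplotypes, BM/BCM identification, trees.

The Kimura two-parameter (K2P) distance corrects the observed proportions
of transitions (P) and transversions (Q) for multiple hits:

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are excluded
pairwise (pairwise deletion, MEGA's default).  Saturated pairs (a log
argument <= 0) yield an undefined distance, reported as NaN and excluded
from the summaries with a count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .containers import PairwiseDistanceMatrix

__all__ = [
    "SequenceRecord",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "base_composition",
    "k2p_distance",
    "p_distance",
    "k2p_matrix",
    "distance_summaries",
    "best_match_identify",
    "nj_tree",
    "bootstrap_support",
    "DistanceSummary",
    "IdentificationOutcome",
    "IdentificationReport",
]

_IUPAC = set("ACGTRYSWKMBDHVN-")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(seq) - _IUPAC
        if bad:
            pos = next(i for i, b in enumerate(seq) if b in bad)
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos + 1} in {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)


class Alignment:
    """Equal-length, gap-aware nucleotide alignment with species labels."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one record")
        length = len(records[0].sequence)
        for r in records:
            if len(r.sequence) != length:
                raise ValueError(
                    f"unequal sequence lengths: {r.id!r} has {len(r.sequence)}, "
                    f"expected {length}"
                )
        self.records = records
        self.length = length

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """Sequences as an (n, L) array of single characters."""
        return np.array([list(r.sequence) for r in self.records])

    def resample_columns(self, columns: np.ndarray) -> "Alignment":
        m = self.matrix()[:, columns]
        return Alignment(
            [
                SequenceRecord(r.id, r.species, "".join(row))
                for r, row in zip(self.records, m)
            ]
        )


def read_fasta(
    path: Union[str, Path],
    species_map: Optional[Mapping[str, str]] = None,
) -> Alignment:
    """Read an aligned FASTA; species from ``>id|species`` headers or a sidecar map."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        seq_id = parts[0]
        species = parts[1] if len(parts) > 1 else None
        if species_map is not None:
            species = species_map.get(seq_id, species)
        if species is None:
            raise ValueError(
                f"no species label for sequence {seq_id!r}: use '>id|species' "
                "headers or provide a species_map"
            )
        records.append(SequenceRecord(id=seq_id, species=species, sequence=str(rec.seq)))
    return Alignment(records)


def write_fasta(aln: Alignment, path: Union[str, Path]) -> None:
    recs = [
        BioSeqRecord(Seq(r.sequence), id=f"{r.id}|{r.species}", description="")
        for r in aln
    ]
    SeqIO.write(recs, str(path), "fasta")


def collapse_haplotypes(aln: Alignment) -> dict:
    """Group sequences by exact (case-insensitive) identity.

    Returns representative id -> list of member ids.  Sequences differing
    only by an ambiguity code are distinct haplotypes.
    """
    groups: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    for r in aln:
        key = r.sequence
        if key not in reps:
            reps[key] = r.id
            groups[r.id] = []
        groups[reps[key]].append(r.id)
    return groups


def base_composition(aln: Alignment) -> dict:
    """Mean per-sequence A/C/G/T frequencies over unambiguous sites."""
    per_seq = []
    for r in aln:
        counts = {b: r.sequence.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            warnings.warn(
                f"sequence {r.id!r} has no unambiguous bases; excluded",
                stacklevel=2,
            )
            continue
        per_seq.append({b: counts[b] / total for b in "ACGT"})
    if not per_seq:
        raise ValueError("no sequences with unambiguous bases")
    return {b: float(np.mean([f[b] for f in per_seq])) for b in "ACGT"}


def _pair_site_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return sites, ts, tv


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance (substitutions/site), pairwise deletion.

    Returns NaN when the correction is undefined (saturation); raises if the
    pair shares no comparable site.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal lengths")
    sites, ts, tv = _pair_site_counts(a, b)
    if sites == 0:
        raise ValueError("no comparable unambiguous sites")
    p, q = ts / sites, tv / sites
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(arg1) - 0.25 * np.log(arg2))


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing comparable sites."""
    sites, ts, tv = _pair_site_counts(a.upper(), b.upper())
    if sites == 0:
        raise ValueError("no comparable unambiguous sites")
    return (ts + tv) / sites


def k2p_matrix(aln: Alignment) -> PairwiseDistanceMatrix:
    """All pairwise K2P distances; ids must be unique."""
    ids = [r.id for r in aln]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(aln)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = k2p_distance(
            aln.records[i].sequence, aln.records[j].sequence
        )
    return PairwiseDistanceMatrix(labels=ids, values=values, metric_name="k2p")


# ---------------------------------------------------------------------------
# distance summaries and the barcoding gap


@dataclass
class DistanceSummary:
    """Intra/interspecific K2P summaries and the barcoding-gap assessment."""

    species: list
    intra_mean: dict  # species -> mean intraspecific distance (NaN if < 2 members)
    intra_max: dict
    inter_mean: dict  # (sp_a, sp_b) -> mean
    inter_max: dict
    max_intra_overall: float
    min_inter_overall: float
    gap_present: bool
    n_undefined: int
    intra_distances: np.ndarray
    inter_distances: np.ndarray

    def histogram(self, bin_width: float = 0.01) -> tuple:
        """Shared-bin counts of intra and inter distances (Fig.-style export)."""
        top = max(
            self.intra_distances.max(initial=0.0),
            self.inter_distances.max(initial=0.0),
        )
        edges = np.arange(0.0, top + 2 * bin_width, bin_width)
        intra_counts, _ = np.histogram(self.intra_distances, bins=edges)
        inter_counts, _ = np.histogram(self.inter_distances, bins=edges)
        return edges, intra_counts, inter_counts


def distance_summaries(aln: Alignment) -> DistanceSummary:
    dm = k2p_matrix(aln)
    labels = np.array([r.species for r in aln])
    species = aln.species
    n = len(aln)
    intra: dict[str, list] = {s: [] for s in species}
    inter: dict[tuple, list] = {}
    n_undefined = 0
    for i, j in combinations(range(n), 2):
        d = dm.values[i, j]
        if np.isnan(d):
            n_undefined += 1
            continue
        si, sj = labels[i], labels[j]
        if si == sj:
            intra[si].append(d)
        else:
            key = tuple(sorted((si, sj)))
            inter.setdefault(key, []).append(d)
    if n_undefined:
        warnings.warn(
            f"{n_undefined} undefined (saturated) pairwise distances excluded",
            stacklevel=2,
        )
    intra_all = np.array([d for v in intra.values() for d in v])
    inter_all = np.array([d for v in inter.values() for d in v])
    if intra_all.size == 0 or inter_all.size == 0:
        raise ValueError(
            "need at least one intraspecific and one interspecific comparison"
        )
    max_intra = float(intra_all.max())
    min_inter = float(inter_all.min())
    return DistanceSummary(
        species=species,
        intra_mean={
            s: float(np.mean(v)) if v else float("nan") for s, v in intra.items()
        },
        intra_max={
            s: float(np.max(v)) if v else float("nan") for s, v in intra.items()
        },
        inter_mean={k: float(np.mean(v)) for k, v in inter.items()},
        inter_max={k: float(np.max(v)) for k, v in inter.items()},
        max_intra_overall=max_intra,
        min_inter_overall=min_inter,
        gap_present=min_inter > max_intra,
        n_undefined=n_undefined,
        intra_distances=intra_all,
        inter_distances=inter_all,
    )


# ---------------------------------------------------------------------------
# best match / best close match identification


@dataclass
class IdentificationOutcome:
    query_id: str
    method: str  # "BM" or "BCM"
    predicted: frozenset  # species of equal-best references
    status: str  # correct / incorrect / ambiguous / no_match
    best_distance: float
    threshold_used: Optional[float] = None


@dataclass
class IdentificationReport:
    outcomes: list
    singletons: list  # query ids of single-member species (no conspecific reference)
    success_rate: float  # correct / evaluated queries
    counts: dict  # status -> count
    threshold: Optional[float]

    @property
    def n_evaluated(self) -> int:
        return len(self.outcomes)


def best_match_identify(
    aln: Alignment,
    method: str = "BM",
    threshold_percentile: float = 95.0,
) -> IdentificationReport:
    """Best match (BM) / best close match (BCM) identification of every sequence.

    Each sequence in turn is the query and all others the references.  BM
    assigns the species of the reference(s) at minimum K2P distance:
    correct if these are exactly the query's species, ambiguous if several
    species tie, otherwise incorrect.  BCM first computes a threshold — the
    stated percentile of all intraspecific pairwise distances — and refuses
    to identify queries whose best match lies beyond it (no_match).
    Ambiguous outcomes count as not-correct in the success rate.  Queries
    from single-member species have no conspecific reference and are
    reported separately, outside the success rate.
    """
    method = method.upper()
    if method not in ("BM", "BCM"):
        raise ValueError("method must be 'BM' or 'BCM'")
    labels = np.array([r.species for r in aln])
    n = len(aln)
    dm = k2p_matrix(aln)

    threshold = None
    if method == "BCM":
        intra = [
            dm.values[i, j]
            for i, j in combinations(range(n), 2)
            if labels[i] == labels[j] and not np.isnan(dm.values[i, j])
        ]
        if not intra:
            raise ValueError("BCM threshold undefined: no intraspecific distances")
        threshold = float(np.percentile(intra, threshold_percentile))

    counts: dict[str, int] = {s: 0 for s in ("correct", "incorrect", "ambiguous", "no_match")}
    outcomes = []
    singletons = []
    species_sizes = {s: int((labels == s).sum()) for s in set(labels.tolist())}
    for i, rec in enumerate(aln):
        if species_sizes[rec.species] < 2:
            singletons.append(rec.id)
            continue
        dists = dm.values[i].copy()
        dists[i] = np.nan
        if np.all(np.isnan(dists)):
            raise ValueError(f"no defined distance for query {rec.id!r}")
        best = np.nanmin(dists)
        hit_species = frozenset(labels[j] for j in np.flatnonzero(dists == best))
        if method == "BCM" and best > threshold:
            status = "no_match"
        elif len(hit_species) > 1:
            status = "ambiguous"
        elif hit_species == {rec.species}:
            status = "correct"
        else:
            status = "incorrect"
        counts[status] += 1
        outcomes.append(
            IdentificationOutcome(
                query_id=rec.id,
                method=method,
                predicted=hit_species,
                status=status,
                best_distance=float(best),
                threshold_used=threshold,
            )
        )
    evaluated = len(outcomes)
    success = counts["correct"] / evaluated if evaluated else float("nan")
    return IdentificationReport(
        outcomes=outcomes,
        singletons=singletons,
        success_rate=success,
        counts=counts,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# trees


def nj_tree(dist: PairwiseDistanceMatrix):
    """Saitou–Nei neighbor joining on a distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the adjacent branch.  Returns an unrooted scikit-bio TreeNode; use
    ``str(tree)`` for Newick.
    """
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    if len(dist.labels) < 3:
        raise ValueError("NJ requires at least 3 taxa")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(dist.values, ids=dist.labels)
    return nj(dm, neg_as_zero=True)


def _bipartitions(tree, tip_set: frozenset) -> set:
    """Canonical non-trivial bipartitions (smaller side, or lexicographic)."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tip_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        parts.add(canonical)
    return parts


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple:
    """Column-resampling bootstrap support for the NJ tree.

    Returns (tree, n_skipped): the NJ tree of the full alignment with
    internal-node names set to percentage support, and the number of
    replicates skipped because a resampled pair had an undefined distance.
    """
    if len(aln) < 4:
        raise ValueError("bootstrap requires at least 4 taxa")
    ids = [r.id for r in aln]
    base_dm = k2p_matrix(aln)
    if np.isnan(base_dm.values).any():
        raise ValueError("full alignment has undefined distances; cannot bootstrap")
    tree = nj_tree(base_dm)
    tip_set = frozenset(ids)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_used = 0
    n_skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = aln.resample_columns(cols)
        try:
            dm = k2p_matrix(rep)
        except ValueError:
            n_skipped += 1
            continue
        if np.isnan(dm.values).any():
            n_skipped += 1
            continue
        n_used += 1
        for part in _bipartitions(nj_tree(dm), tip_set):
            counts[part] = counts.get(part, 0) + 1

    if n_used == 0:
        raise ValueError("all bootstrap replicates degenerate")
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tip_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * counts.get(canonical, 0) / n_used
        node.name = f"{support:.0f}"
    return tree, n_skipped
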