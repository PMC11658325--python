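"""End-to-end orchestration of the morphometric and barcode tracks.

Each runner executes its full analysis chain and writes plain-text
artifacts (CSV tables, Newick trees, JSON summaries) into an output
directory, together with a run log carrying the seed and a hash of the
configuration so reruns are reproducible and attributable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import barcode as bc
from . import classify, io, shapestats
from .containers import MorphoDataset
from .gpa import centroid_size, gpa, repeatability

__all__ = ["RunConfig", "run_morpho", "run_barcode", "run_all"]


@dataclass
class RunConfig:
    landmarks_path: Optional[str] = None
    landmarks_format: str = "csv"  # csv or tps
    fasta_path: Optional[str] = None
    output_dir: str = "wingid_out"
    seed: int = 0
    n_permutations: int = 1000
    bcm_percentile: float = 95.0
    n_components: Optional[int] = None
    allometric_correction: bool = False
    bootstrap_replicates: int = 0
    flip_y: bool = False

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_log(config: RunConfig, out: Path, name: str, entries: dict) -> None:
    log = {"config": asdict(config), "config_hash": config.hash(), "seed": config.seed}
    log.update(entries)
    (out / name).write_text(json.dumps(log, indent=2, default=str) + "\n")


def _load_landmarks(config: RunConfig) -> MorphoDataset:
    if config.landmarks_path is None:
        raise ValueError("no landmark input configured")
    if config.landmarks_format == "tps":
        return io.read_tps(config.landmarks_path, flip_y=config.flip_y)
    return io.read_landmark_csv(config.landmarks_path)


def _allometry_corrected_scores(shape_vars, aligned, labels):
    """Pooled within-group regression residuals of scores on log CS (optional)."""
    x = shape_vars.scores
    log_cs = np.log(aligned.centroid_sizes)
    resid = x.copy()
    centred_cs = np.empty_like(log_cs)
    for s in set(labels.tolist()):
        mask = labels == s
        centred_cs[mask] = log_cs[mask] - log_cs[mask].mean()
        resid[mask] -= x[mask].mean(axis=0)
    slope = np.linalg.lstsq(
        centred_cs[:, None], resid, rcond=None
    )[0]
    corrected = x - np.outer(centred_cs, slope[0])
    return corrected


def run_morpho(config: RunConfig, dataset: Optional[MorphoDataset] = None) -> dict:
    """Full morphometric track; returns the results and writes the bundle.

    Chain: repeatability (when replicates are present) -> GPA -> allometry
    -> size permutation ANOVA -> shape PCA -> discriminant factor map ->
    Mahalanobis matrix + permutation tests -> UPGMA phenogram -> jackknife
    classification by size and by shape.
    """
    out = _outdir(config)
    if dataset is None:
        dataset = _load_landmarks(config)

    results: dict = {"stage": "start"}
    has_replicates = any(c.replicate is not None for c in dataset)
    if has_replicates:
        results["repeatability"] = repeatability(dataset)
        (out / "repeatability.json").write_text(
            json.dumps(
                {
                    "R": results["repeatability"].R,
                    "measurement_error": results["repeatability"].measurement_error,
                    "n_individuals": results["repeatability"].n_individuals,
                    "n_replicates": results["repeatability"].n_replicates,
                },
                indent=2,
            )
            + "\n"
        )
        # The statistical chain below assumes one configuration per specimen.
        first = {}
        for i, c in enumerate(dataset):
            first.setdefault(c.specimen_id, i)
        dataset = dataset.subset(sorted(first.values()))

    aligned = gpa(dataset)
    labels = aligned.species_labels

    allom = shapestats.allometry_test(
        aligned, n_permutations=config.n_permutations, seed=config.seed
    )
    results["allometry"] = allom
    (out / "allometry.json").write_text(
        json.dumps(
            {
                "r_squared": allom.r_squared,
                "slope": allom.slope,
                "intercept": allom.intercept,
                "p_value": allom.p_value,
            },
            indent=2,
        )
        + "\n"
    )

    anova = shapestats.size_permutation_anova(
        dataset, n_permutations=config.n_permutations, seed=config.seed
    )
    results["size_anova"] = anova
    pd.DataFrame(
        {
            "species": anova.species,
            "n": anova.ns,
            "mean_cs_mm": np.round(anova.means, 3),
            "sd_cs_mm": np.round(anova.sds, 3),
            "min_cs_mm": np.round(anova.mins, 3),
            "max_cs_mm": np.round(anova.maxs, 3),
            "letters": [anova.letters[s] for s in anova.species],
        }
    ).to_csv(out / "size_summary.csv", index=False)

    shape_vars = shapestats.shape_pca(aligned)
    scores = shape_vars.scores
    if config.allometric_correction:
        scores = _allometry_corrected_scores(shape_vars, aligned, labels)
    if config.n_components is not None:
        scores = scores[:, : config.n_components]
    results["shape_vars"] = shape_vars

    cva = shapestats.discriminant_map(scores, labels)
    results["cva"] = cva
    factor = pd.DataFrame(
        cva.scores[:, : min(2, cva.scores.shape[1])],
        columns=[f"cv{i + 1}" for i in range(min(2, cva.scores.shape[1]))],
    )
    factor.insert(0, "species", labels)
    factor.insert(0, "specimen_id", aligned.specimen_ids)
    factor.to_csv(out / "factor_map.csv", index=False)

    mahal = shapestats.mahalanobis_matrix(scores, labels)
    perms = shapestats.mahalanobis_permutation_tests(
        scores, labels, n_permutations=config.n_permutations, seed=config.seed
    )
    results["mahalanobis"] = mahal
    results["mahalanobis_tests"] = perms
    table3 = mahal.to_dataframe().round(2).astype(str)
    for (a, b), test in perms.items():
        star = "*" if test.p_adjusted < 0.05 else ""
        table3.loc[a, b] = table3.loc[b, a] = f"{mahal[(a, b)]:.2f}{star}"
    table3.to_csv(out / "mahalanobis.csv")

    newick = shapestats.upgma(mahal)
    results["upgma"] = newick
    (out / "upgma.nwk").write_text(newick + "\n")

    size_cm = classify.jackknife_size(dataset)
    shape_cm = classify.jackknife_shape(scores, labels)
    results["jackknife_size"] = size_cm
    results["jackknife_shape"] = shape_cm
    acc = pd.DataFrame(
        {
            "species": size_cm.labels,
            "n": size_cm.class_sizes,
            "size_accuracy_pct": np.round(100 * size_cm.per_class_accuracy, 2),
            "shape_accuracy_pct": np.round(100 * shape_cm.per_class_accuracy, 2),
        }
    )
    acc.loc[len(acc)] = [
        "TOTAL",
        size_cm.counts.sum(),
        round(100 * size_cm.overall_accuracy, 2),
        round(100 * shape_cm.overall_accuracy, 2),
    ]
    acc.to_csv(out / "classification_accuracy.csv", index=False)
    shape_cm.to_dataframe().to_csv(out / "confusion_shape.csv")
    size_cm.to_dataframe().to_csv(out / "confusion_size.csv")

    _write_log(
        config,
        out,
        "morpho_run.json",
        {
            "n_specimens": len(dataset),
            "n_species": len(set(labels.tolist())),
            "gpa_iterations": aligned.iterations,
            "gpa_converged": aligned.converged,
            "shape_dimensions": scores.shape[1],
            "size_accuracy": size_cm.overall_accuracy,
            "shape_accuracy": shape_cm.overall_accuracy,
        },
    )
    return results


def run_barcode(config: RunConfig, aln: Optional[bc.Alignment] = None) -> dict:
    """Full barcode track; returns the results and writes the bundle.

    Chain: haplotypes -> base composition -> K2P distance summaries with
    barcoding-gap histogram -> BM/BCM identification -> NJ tree (optional
    bootstrap).
    """
    out = _outdir(config)
    if aln is None:
        if config.fasta_path is None:
            raise ValueError("no FASTA input configured")
        aln = bc.read_fasta(config.fasta_path)

    results: dict = {}
    haplos = bc.collapse_haplotypes(aln)
    results["haplotypes"] = haplos
    pd.DataFrame(
        [(rep, len(members), ";".join(members)) for rep, members in haplos.items()],
        columns=["representative", "n_members", "members"],
    ).to_csv(out / "haplotypes.csv", index=False)

    comp = bc.base_composition(aln)
    results["base_composition"] = comp
    pd.DataFrame([comp]).round(4).to_csv(out / "base_composition.csv", index=False)

    summary = bc.distance_summaries(aln)
    results["distance_summary"] = summary
    species = summary.species
    table6 = pd.DataFrame(index=species, columns=species, dtype=object)
    for s in species:
        table6.loc[s, s] = (
            f"{100 * summary.intra_mean[s]:.2f} ({100 * summary.intra_max[s]:.2f})"
            if not np.isnan(summary.intra_mean[s])
            else "n/a"
        )
    for (a, b), mean in summary.inter_mean.items():
        cell = f"{100 * mean:.2f} ({100 * summary.inter_max[(a, b)]:.2f})"
        table6.loc[a, b] = table6.loc[b, a] = cell
    table6.to_csv(out / "k2p_distances_pct.csv")

    edges, intra_counts, inter_counts = summary.histogram()
    pd.DataFrame(
        {
            "bin_left_pct": np.round(100 * edges[:-1], 2),
            "bin_right_pct": np.round(100 * edges[1:], 2),
            "intraspecific": intra_counts,
            "interspecific": inter_counts,
        }
    ).to_csv(out / "gap_histogram.csv", index=False)

    reports = {}
    for method in ("BM", "BCM"):
        rep = bc.best_match_identify(
            aln, method=method, threshold_percentile=config.bcm_percentile
        )
        reports[method] = rep
    results["identification"] = reports
    rows = []
    for method, rep in reports.items():
        for o in rep.outcomes:
            rows.append(
                (
                    method,
                    o.query_id,
                    ";".join(sorted(o.predicted)),
                    o.status,
                    round(o.best_distance, 6),
                )
            )
    pd.DataFrame(
        rows, columns=["method", "query_id", "predicted", "status", "best_distance"]
    ).to_csv(out / "identification.csv", index=False)
    (out / "identification_summary.json").write_text(
        json.dumps(
            {
                method: {
                    "success_rate": rep.success_rate,
                    "counts": rep.counts,
                    "n_evaluated": rep.n_evaluated,
                    "n_singletons": len(rep.singletons),
                    "threshold": rep.threshold,
                }
                for method, rep in reports.items()
            },
            indent=2,
        )
        + "\n"
    )

    dm = bc.k2p_matrix(aln)
    if dm.n_undefined == 0 and len(aln) >= 3:
        if config.bootstrap_replicates > 0 and len(aln) >= 4:
            tree, skipped = bc.bootstrap_support(
                aln, n_replicates=config.bootstrap_replicates, seed=config.seed
            )
            results["bootstrap_skipped"] = skipped
        else:
            tree = bc.nj_tree(dm)
        newick = str(tree).strip()
        results["nj"] = newick
        (out / "nj.nwk").write_text(newick + "\n")
    else:
        warnings.warn("NJ tree skipped: undefined distances or too few taxa")

    _write_log(
        config,
        out,
        "barcode_run.json",
        {
            "n_sequences": len(aln),
            "n_species": len(aln.species),
            "n_haplotypes": len(haplos),
            "gap_present": summary.gap_present,
            "bm_success_rate": reports["BM"].success_rate,
            "bcm_success_rate": reports["BCM"].success_rate,
        },
    )
    return results


def run_all(
    config: RunConfig,
    dataset: Optional[MorphoDataset] = None,
    aln: Optional[bc.Alignment] = None,
) -> dict:
    """Run both tracks and write the headline method comparison."""
    out = _outdir(config)
    combined: dict = {}
    notices = []
    try:
        combined["morpho"] = run_morpho(config, dataset=dataset)
    except ValueError as err:
        notices.append(f"morpho track skipped: {err}")
    try:
        combined["barcode"] = run_barcode(config, aln=aln)
    except ValueError as err:
        notices.append(f"barcode track skipped: {err}")
    if not combined:
        raise ValueError("no input for either track; " + "; ".join(notices))

    rows = []
    if "morpho" in combined:
        rows.append(
            (
                "wing size (jackknife ML)",
                round(100 * combined["morpho"]["jackknife_size"].overall_accuracy, 2),
            )
        )
        rows.append(
            (
                "wing shape (jackknife Mahalanobis)",
                round(100 * combined["morpho"]["jackknife_shape"].overall_accuracy, 2),
            )
        )
    if "barcode" in combined:
        reports = combined["barcode"]["identification"]
        rows.append(("COI barcode BM", round(100 * reports["BM"].success_rate, 2)))
        rows.append(("COI barcode BCM", round(100 * reports["BCM"].success_rate, 2)))
    pd.DataFrame(rows, columns=["method", "accuracy_pct"]).to_csv(
        out / "method_comparison.csv", index=False
    )
    _write_log(config, out, "combined_run.json", {"notices": notices})
    combined["notices"] = notices
    return combined
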