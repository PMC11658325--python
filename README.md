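# wingid

Species identification of human-biting black flies (*Simulium*, Diptera:
Simuliidae) from two independent lines of evidence, implemented as one
tested pipeline:

1. **Wing geometric morphometrics** — landmark-based analysis of wing size
   and wing shape, with jackknife-validated classification.
2. **COI DNA barcoding** — Kimura two-parameter distance evaluation of
   658-bp cytochrome *c* oxidase I barcodes, with best match / best close
   match identification.

Black flies are vectors of *Onchocerca* and other pathogens; reliable
species identification is the entry point of any vector study, yet adult
females of many species are nearly indistinguishable morphologically. Wing
venation landmarks are cheap to digitize and shape is a strong
species-level signal; barcodes are more accurate but costlier. This package
implements both tracks so their accuracy can be compared on the same
specimen design, and ships a seeded synthetic-data generator emulating a
seven-species, 253-wing, 70-barcode study so every stage is testable
without any data download.

## The statistics at the core

**Size.** Centroid size `CS = sqrt(Σ_i ||x_i − x̄||²)` over the k = 10
landmarks; species differences tested by permutation one-way ANOVA
(1000 iterations, Bonferroni-adjusted pairwise tests, compact letter
display).

**Shape.** Generalized Procrustes analysis (GPA): each configuration is
centred, scaled to unit CS, and rotated (never reflected) onto an iterated
consensus; aligned shapes are projected into the Kendall tangent space,
where principal-component scores serve as shape variables (16 dimensions
for 10 landmarks). Between-species divergence is the Mahalanobis distance
`D_ij = sqrt((m_i − m_j)ᵀ S⁻¹ (m_i − m_j))` with S the pooled within-group
covariance, tested by within-pair label permutation; canonical variate axes
give the factor map and a UPGMA phenogram summarizes the D matrix.
Digitizing quality is quantified by a two-level Procrustes ANOVA
repeatability index `R = var_among / (var_among + var_within)`, and the
size–shape coupling (allometry) by the R² of PC1 on CS.

**Validated classification.** Leave-one-out: by size, maximum-likelihood
assignment under species-specific normal CS distributions; by shape,
nearest species by Mahalanobis distance with leave-one-out means and pooled
covariance.

**Barcodes.** K2P distance
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` (P transitions, Q transversions,
pairwise deletion of ambiguous sites); haplotype collapsing; intra- vs
interspecific distance summaries and the barcoding-gap check
(`min inter > max intra`); best match (BM) assigns each query the species
of its nearest reference, best close match (BCM) additionally refuses
matches beyond the 95th percentile of intraspecific distances;
neighbor-joining tree with optional column bootstrap.

## Worked example

```sh
wingid simulate-morpho --out wings.csv --seed 1     # 253 wings, 7 species
wingid simulate-coi    --out coi.fasta --seed 1     # 70 x 658 bp barcodes
wingid compare --landmarks wings.csv --fasta coi.fasta --out-dir results --seed 1
cat results/method_comparison.csv
```

prints

```
method,accuracy_pct
wing size (jackknife ML),58.1
wing shape (jackknife Mahalanobis),83.4
COI barcode BM,100.0
COI barcode BCM,100.0
```

— the package's central comparison: wing *shape* classifies far better
than wing *size* (83% vs 58% of 253 specimens correctly re-identified
under leave-one-out), and the barcode track is better still (70/70 on this
well-separated synthetic set). `results/` also contains the per-species
size table with significance letters (`size_summary.csv`), the Mahalanobis
matrix with permutation stars (`mahalanobis.csv`), the UPGMA phenogram
(`upgma.nwk`), confusion matrices, the K2P distance table in percent
(`k2p_distances_pct.csv`), barcoding-gap histogram data and the NJ tree.
Everything is plain text and reruns byte-identically under the same seed.

The same analyses are available as library functions (`wingid.gpa`,
`wingid.shape_pca`, `wingid.mahalanobis_matrix`, `wingid.jackknife_shape`,
`wingid.k2p_distance`, `wingid.best_match_identify`, ...) operating on TPS,
CSV or FASTA input.

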