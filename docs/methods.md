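# Methods

## Superimposition and shape variables

Shape analysis uses the partial Procrustes convention: every configuration
is centred, scaled to unit centroid size, and rotated onto the consensus by
the rotation (determinant +1) minimizing the Frobenius norm. Reflections
are never allowed — wing datasets are prepared from one body side, and a
reflected fit would silently absorb digitization of the wrong side.
Convergence is declared when the consensus root-mean-square change drops
below 1e-8 (at most 100 iterations; non-convergence is flagged on the
result, not raised). After the final pass the consensus is recomputed as
the normalized mean of the aligned shapes, so the subsequent tangent
projection — removal of the component along the consensus vector — zeroes
the column means of the tangent coordinates exactly rather than only
approximately.

Shape variables are principal-component scores of the tangent coordinates.
Classical presentations use thin-plate-spline partial-warp scores here, but
every downstream statistic in this package (Mahalanobis distance, canonical
variates, jackknife classification) is exactly invariant to replacing one
full-rank linear transform of the tangent space by another, so PCA scores
are statistically interchangeable with partial warps; the test suite
asserts this invariance directly. For k two-dimensional landmarks the
tangent space has 2k − 4 dimensions (16 for the 10-landmark wing), and the
PCA retains exactly the components with non-negligible variance (relative
eigenvalue tolerance 1e-9).

## Repeatability

Digitizing quality is a two-level Procrustes ANOVA on the jointly
superimposed replicate digitizations: sums of squares of tangent
coordinates are partitioned into among-individual and within-individual
components (the decomposition is exact and tested to 1e-10). Variance
components follow the expected mean squares — `var_within = MS_within`,
`var_among = (MS_among − MS_within)/r₀` floored at zero, with r₀ the
effective replicate count (equal to r for balanced designs) — and
`R = var_among/(var_among + var_within)`. When both components are zero
(identical individuals digitized identically) R is defined as 1.

## Permutation tests

All significance testing is by permutation with the finite-sample
correction `p = (#{stat_perm ≥ stat_obs} + 1)/(N + 1)`, so p-values are
never zero, and Bonferroni is the only multiplicity adjustment (g(g−1)/2
pairs; 21 for seven species). A practical floor follows: with N
permutations the smallest achievable raw p is 1/(N+1), so at least 420
permutations are needed before any of 21 Bonferroni-adjusted pairwise
tests can reach 0.05; the default is 1000 throughout. The pairwise
Mahalanobis test permutes labels within the pair and recomputes D from the
pair-pooled covariance; the reported distance matrix instead pools the
within-group covariance over all groups (n − g denominator). A singular
pooled covariance triggers ridge shrinkage `S + λI` with
`λ = 1e-8 · trace(S)/d` and a logged warning; the matrix constructor
refuses outright when n − g < d.

Compact letters for the size table are one letter per maximal clique of
the "not significantly different" graph (Bron–Kerbosch; trivially fast at
these group counts), ordered by group mean.

## Classification

Jackknife (leave-one-out) throughout. The size classifier fits a normal
per species with species-specific variance — the observed per-species CS
spreads differ enough that pooling would misstate the likelihoods. The
shape classifier recomputes group means and the pooled covariance without
the held-out specimen on every fold (a naive refit; at n ≈ 253, d = 16
this costs well under a second and avoids downdating-formula bugs).
Superimposition itself is *not* redone per fold: one specimen's influence
on a 253-wing consensus is negligible, and refitting GPA per fold would
change no assignment while multiplying the cost. Ties in likelihood or
distance go to the first species in canonical label order, making output
deterministic.

## Allometry

The size–shape relation is the OLS of PC1 on CS, summarized by R², with a
permutation p (CS permuted against PC1). PC1's sign is arbitrary; the
package fixes it by making each component's largest-magnitude loading
positive, so the reported slope sign is reproducible but only meaningful
relative to that orientation. Wing size is *excluded* from the shape
variables by default (no allometric residualization), since size is
environmentally labile while shape is the species-level signal; a pooled
within-group regression residual correction is available behind
`allometric_correction` for sensitivity analysis.

## Trees

UPGMA is implemented directly (average linkage with cluster-size weights,
merge height = distance/2, ties broken by the lexicographically smallest
member-label pair, branch lengths printed to 10 significant digits); it is
cross-checked against SciPy's average-linkage cophenetic distances in the
tests. Neighbor joining delegates to scikit-bio's Saitou–Nei
implementation (negative branch lengths clamped to zero with the deficit
moved to the adjacent branch); the tests verify exact recovery of additive
distances. Bootstrap support resamples alignment columns, rebuilds the NJ
tree, and maps canonical bipartition frequencies onto the full-data tree;
replicates with saturated (undefined) distances are skipped and counted.

## Barcode conventions

K2P distances use pairwise deletion (sites with a gap or ambiguity in
either sequence are dropped for that pair), matching the common
MEGA-style treatment; this choice changes distance tables and is therefore
fixed, not configurable. Saturation (log argument ≤ 0) yields NaN, which
summaries exclude with a count rather than silently dropping. Haplotype
identity is exact full-length string identity (case-insensitive);
sequences differing only by an N are distinct haplotypes, since no
principled merging rule exists without quality data. The BCM threshold is
the 95th percentile of all intraspecific pairwise distances (configurable);
ambiguous best-match ties count as not-correct in the success rate, and
queries from single-member species are reported separately instead of
polluting the rate. Identification summaries default to all sequences
rather than unique haplotypes — duplicate references are legitimate
evidence of intraspecific variance — and the BM rate is invariant to
reference duplication anyway (asserted in tests).

## The synthetic-data generator

Landmarks: each specimen is the fixed 10-landmark wing template plus a
species offset, an allometric displacement, and isotropic within-species
noise, scaled to a centroid size drawn per species, then digitized with
independent per-coordinate error. Species offsets default to mutually
orthogonal directions of shape space (deterministically constructed,
orthogonal to translation/scale/rotation of the template), so the true
between-species Mahalanobis separation is controllable:
`D_ij ≈ sqrt(δ_i² + δ_j²)/σ_within`. Default study conditions: the seven
species with their observed sample sizes (50/30/39/31/39/31/33 = 253) and
centroid-size means ± SDs (2.19–3.53 ± 0.09–0.19 mm); offset magnitudes
graded from 0.018 to 0.040 shape units against within_sd = 0.01 to give
pairwise D between ~2.5 and ~6, with the most isolated species most
distinct; allometric slope −0.08 shape units per log-mm (a modest negative
size–shape coupling, R² ≈ 25–35% on the full design); digitizing SD
0.003 mm (≈ 1/10 of biological shape variation at these wing sizes, giving
R ≈ 0.99).

Sequences: a Kimura-type per-site process with transition/transversion
rate ratio κ = 4 (typical of insect mitochondrial protein-coding genes),
applied via the exact K80 transition probabilities. One ancestral 658-bp
sequence is drawn from an AT-rich composition (A .275, C .178, G .168,
T .379); each species centroid evolves divergence/2 = 0.07 expected
substitutions/site from it; individuals evolve θ = 0.005 from their
centroid (intraspecific means ≈ 1%, interspecific ≈ 14–16%).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: correlated (anatomically structured) landmark
covariance; species complexes and introgression, so every simulated
species is monophyletic with a clean barcoding gap, whereas real barcode
sets can lack one; shared haplotypes (the per-individual mutation model
makes nearly every simulated sequence unique); rate variation across
sites; indels and sequencing ambiguities. Results on synthetic data
demonstrate the estimators are correct and calibrated, not that any
particular field accuracy will be achieved.

## Problem sizes in the test suite

Calibration checks use Monte-Carlo sizes chosen for stable pass/fail
behaviour at desk scale: the allometry type-I rate uses 100 replicates of
200 permutations; the Mahalanobis null calibration 100 replicates of 400
permutations; the size-vs-shape comparison 20 replicates of the full
253-wing design. The acceptance script runs each track once at the full
default design.

## Known limitations

* TPS import supports LM=/ID=/SCALE=/IMAGE= records only; 3-D landmarks,
  semilandmarks and missing-landmark imputation are out of scope.
* Mixed y-axis conventions (image vs mathematical) within one dataset
  cannot be detected; `flip_y` applies to a whole file.
* Datasets are in-memory; nothing is streamed.
* The size classifier's normal model is a choice, not a fact; heavy-tailed
  CS distributions would need a different likelihood.
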