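# Methods

## Model and procedure

The package treats log-normalised expression as additively composed of a
population (cluster) effect, a batch effect, optional extra covariate
effects, and a cellular-detection-rate (CDR) effect:

    E_ijk = C_j,z(i) + B_jk + T_ij + R_i        (gene j, cell i, batch k)

The core quantity is the similarity between two batch-specific cell groups.
For a pair (g_i, g_j'), a working set is assembled from the two groups (each
downsampled to a common size) and a shared background drawn equally from
every other initial cluster. One ordinary-least-squares fit per gene with
treatment-coded covariates — group (three levels, background as reference),
batch, extras, scaled CDR — yields each group's differential-expression
signature d = contrast(group − background), a vector of log2 fold-changes.
The similarity is the Pearson correlation of the two signatures. Because
batch sits in the model, any per-gene additive batch shift moves only the
batch coefficients and leaves the signatures exactly unchanged (verified to
1e-8 end to end in the test-suite).

Clustering merges initial clusters (per-batch Louvain communities, or batch
tag x annotation) by complete-linkage agglomeration on distance 1 − S, so
the most similar groups merge first, and cuts the tree at `cut_height`.
Within-batch pairs are never compared; their distance is imputed as 1, on
the grounds that within-batch clustering already separated them.

Evaluation of an integration result inverts the logic: corrected-space
clusters are split into batch-specific subclusters, scored by cross-batch
similarity on the *original* expression, and compared against a background
distribution of within-population similarity obtained by repeatedly halving
the mutually-nearest, most-similar subcluster pair. The rejection
probability is the add-one-smoothed upper-tail empirical probability
p = (#{b > observed} + 1)/(B + 1): close to 1 when the observed similarity
falls below what one population produces by sampling variation alone.

## Assumptions

* Confounders act (approximately) additively on the log scale. The
  regress-out guarantee is exact only for exactly additive shifts; real
  batch effects on weakly expressed genes (zeros stay zero under log1p) are
  absorbed only approximately.
* Within one batch, the confounder is constant, so within-batch clustering
  reflects population structure.
* For evaluation: the mutually-nearest, highest-similarity subcluster pair
  is a genuine population ("mutual nearest" hypothesis), and
  within-population variability is roughly constant across populations
  ("constant variability" hypothesis), licensing one shared background
  distribution per analysis.

## Background-composition geometry and the merge cut

A signature is referenced to the *average of its own batch's background*:
with a single background level the model cannot separate the batch effect
from between-batch differences in background composition, so for the pair
(g_i in batch a, g_j' in batch b),

    d_i  ≈ δ_g − mean(δ of batch-a's other populations)
    d_j' ≈ δ_g − mean(δ of batch-b's other populations).

When the two batches share no populations beyond the compared one — the
worst case of non-identical composition — the two subtracted means are
independent, and with two other populations per batch of equal effect
variance v the same-population correlation has the *ceiling*
cov/var = v/(1.5 v) = 2/3, independent of effect size. Shared background
populations raise the ceiling (one of two shared: 1.25v/1.5v ≈ 0.83);
estimator noise lowers everything multiplicatively. Cross-population pairs
live near 0 (at most ~v/4 of shared-background covariance, and can be
negative when the partner population sits in the other group's background).

The default `cut_height = 0.6` (merge at similarity ≥ 0.4) follows from this
geometry: it admits same-population pairs down to the disjoint-background
ceiling times realistic noise attenuation, while staying above the
cross-population regime. Correctly aligned cross-species populations can
score as low as ≈ 0.4, which a stricter cut would refuse to merge. The full
dendrogram is always emitted, so any analysis can be re-cut without
recomputation, and the cut is exposed prominently in the configuration.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_genes` | 500 | minimum detected genes per kept cell |
| `scale`, pseudocount | 1e4, 1 | library-size normalisation: log2(1 + 1e4·c/lib) |
| `n_hvgs` | 2000 | genes for per-batch PCA (binned standardized dispersion, ties by gene id) |
| `n_pcs` | 10 | PCs for the SNN graph |
| `resolution` | 0.4 | Louvain resolution for initial clustering |
| `snn_k` | 20 | SNN neighbourhood size (Jaccard weights, prune < 1/15) |
| `target` (downsample) | 40 | cells per group in each comparison; midpoint of the sensible 35–50 range; a warning fires below 15 cells (sampling with replacement) |
| background cap | 10 × target | equal draws per other cluster, bounding cost |
| `min_detect_frac` | 0.05 | genes must be detected in ≥ 5% of the working set |
| `premerge_threshold` | 0.9 | within-batch merge bar for de novo initial clusters |
| `cut_height` | 0.6 | merge bar on distance 1 − S (see above) |
| `min_cluster_size` | 75 | HDBSCAN minimum for corrected-space partitioning |
| `min_cells` | 15 | smallest evaluable batch-specific subcluster |
| `n_splits` | 20 | background samples for the rejection probability |
| `perplexity` | 30 | Gaussian-kernel bandwidth target for cLISI |

## Numerical choices

* One QR factorisation of the design is shared by all genes; coefficients,
  residual variances and the unscaled contrast variance come from it.
* Design columns are scanned in the order intercept → group → batch →
  covariates → CDR; constant or linearly dependent columns are dropped with
  a warning, so covariates are sacrificed before batch and batch before
  group. A dependent *group* column raises an error (the effect of interest
  is inestimable).
* Empirical-Bayes moderation (markers): the per-gene prior variance is
  exp(lowess(log s² ~ mean expression)) and the prior degrees of freedom
  come from a method-of-moments fit on the log-variance residuals
  (trigamma inversion by Newton iteration). This deliberately skips the
  log-scale bias correction some implementations apply, so that a flat
  variance landscape is left exactly untouched by shrinkage. Moderation is
  the gene-level ("trend") form throughout; observation-level precision
  weights are out of scope. Moderation does not affect similarities — the
  contrast coefficients are identical either way.
* The complete-linkage agglomeration is implemented directly (k is the
  number of initial clusters, so O(k³) is negligible) to guarantee a
  deterministic tie-break: ties in merge distance resolve by the
  lexicographically smallest sorted pair of member-label tuples. An
  independent implementation (scipy) is the oracle in the tests.
* All randomness flows from one seed through named substreams
  (SHA-256 of seed plus labels): each pair's downsampling is keyed by the
  sorted pair labels, so the similarity matrix is independent of pair
  order and worker count; each background split is keyed by its index.
* cLISI tunes a per-cell Gaussian-kernel bandwidth by bisection on the
  neighbourhood entropy (target log perplexity, 3x perplexity nearest
  neighbours); exact duplicate points fall back to uniform kNN weights.
* Leave-one-out influence down-dates the five correlation sufficient sums
  (O(G) total); a degenerate leave-one-out vector records a missing
  influence. Correlations at ±1 are clipped to 1 − 1e-12 before the
  Fisher transform.
* Similarity of a zero-variance signature is an error, never silently 0.

## Background splits for the rejection probability

Each background sample scores a random half of one batch-specific anchor
subcluster against a random half of the other, so every pseudo-group is
single-batch — exactly the structure of a real evaluated pair — while the
background cells in the fit keep the batch covariate estimable. Mixed-batch
halves were tried first and rejected: averaging batches within each
pseudo-group cancels batch noise that every real cross-batch pair does
carry, concentrating the null strictly above even perfectly aligned pairs
and saturating the rejection probability at 1 for every cluster. Note the
probability is granular (multiples of 1/(B+1)) and saturates at 1 for any
cluster below the whole background sample; the similarity itself remains
the primary discriminating score, with the probability as its calibrated
summary.

## What the simulator does and does not emulate

`simulate_counts` draws counts from a gamma-Poisson hierarchy with additive
log2-scale effects: gene base means λ_j ~ Gamma(0.6, 4); population effects
δ ~ N(0, de_sigma) on a `de_prob` fraction of genes (default 10%); batch
effects ε ~ N(0, batch_sigma) on *all* genes — the asymmetry the regress-out
step exploits; optional nested per-batch covariates (e.g. donors); library
factors LogNormal(0, 0.35). It reproduces the structure the clustering
method targets — distinct populations, global additive confounders, known
truth — but not dropout beyond Poisson sampling, doublets, trajectories, or
gene–gene correlation. Passing tests therefore demonstrate correct behaviour
under additive confounding, not robustness to every artefact of real data.

Scenario presets fix the study conditions. The five-population /
three-batch scenario applies the canonical removal pattern (batch 1 keeps
populations {1,2,3}, batch 2 {2,3,4}, batch 3 {2,4,5}; only population 2 is
everywhere) with 250 cells per block (~2250 cells) and 1000 genes. Its
effect scales — de_sigma = 2.0, batch_sigma = 0.5 — were calibrated once so
that (i) populations are cleanly separable within batch at Louvain
resolution 0.4, the structure the scenario is meant to depict, and (ii)
pooled uncorrected clustering is visibly confounded by batch
(ARI_population ≈ 0.58 versus 1.0 for both meta-clustering workflows).
Note that on this composition population and batch are correlated *by
design*: the ground-truth partition itself has ARI_batch = 0.159, which is
therefore the floor for any accurate clustering. The overcorrection fixture
plants the canonical false alignment — population 3 exists only in batch A
and population 4 only in batch B, and the synthetic "corrected" embedding
collapses them onto one blob — with a generator self-check that the two
populations' true signatures correlate below 0.3.

## Problem sizes

The bundled experiments run at desk scale: 2250 cells x 1000 genes for the
clustering scenario (10 replicates), 450-cell mixture designs for the
similarity-ordering experiment, and 900-cell two-batch fixtures for
evaluation. These sizes give stable estimates (the pairwise similarity
stage depends on the number of initial clusters, not cells, once groups are
downsampled) while keeping a full reproduction run around a minute.

## Known limitations

* The background-composition ceiling (above) means similarities between the
  same population in batches with disjoint co-populations cannot approach 1
  even noise-free; interpret raw similarity levels relative to the design,
  or re-cut the emitted dendrogram.
* With very few initial clusters (e.g. a single batch with three groups)
  the background is a single population and its signature leaks into both
  compared groups, inflating similarity; the metric is designed for
  analyses with a reasonably broad background.
* The rejection probability needs ≥ 2 sufficiently large batch-specific
  subclusters per cluster; single-batch clusters are reported as
  non-evaluable rather than scored.
* Runtime of the pairwise stage is quadratic in the number of initial
  clusters.
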