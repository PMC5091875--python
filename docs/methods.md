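# Methods

## The integration model

The pipeline assumes that each omics platform carries *blocks* of
co-varying features, and that a block's joint signal splits the cohort in
two (carriers vs non-carriers of an amplification, a hypermethylation
event, an expression program, …). A sample's molecular identity is then a
binary code over all blocks of all platforms, and subgroups are clusters
of those codes. This motivates the three-stage design: feature
sub-clustering recovers the blocks, per-block two-way sample splits
recover the code bits, and consensus clustering of the stacked bits calls
the subgroups. Because the code is binary per block, the method is
insensitive to the widely different feature counts and scales of the
platforms — each platform contributes in proportion to its number of
sub-clusters, which is exactly the quantity the survival-guided grid
search selects.

Indicator rows whose two-way split would produce a group smaller than 10
samples are set entirely to NA: a split supported by fewer than 10 samples
is more likely noise than a reproducible molecular dichotomy, and the
NA-tolerant distance simply ignores those rows.

## Per-platform preprocessing

| platform | transform | floor/clip | variance filter |
|---|---|---|---|
| CNV | length-weighted mean of log₂ segment means over each gene interval | clip to ±2 | keep genes with SD > 0.2 |
| methylation | beta values as-is | — | drop loci with any NA, keep top 10 000 by SD |
| mRNA | log₂ of scaled estimates | floor −26 (zeros map to the floor) | drop undetected genes, keep top 6 000 by SD |
| miRNA | log₂ RPM | floor 0 | drop undetected miRNAs, keep top 80 by SD |
| mutation | gene × sample 0/1 | — | drop never-mutated genes |

SD is always the sample standard deviation (n − 1). Top-N selection
orders by descending SD with ties broken lexicographically by feature ID,
so runs are bit-reproducible. The CNV gene score defaults to
length-weighting because it is robust to fragmented segmentation; an
unweighted per-segment mean is available via
`PreprocessConfig(cnv_length_weighted=False)`.

Coordinate conventions: SEG files are read as 1-based inclusive, BED gene
models as 0-based half-open and converted on read; chromosome names are
normalized by stripping a `chr` prefix so the two join correctly.

## Clustering choices

The literature behind this family of methods does not fix the clustering
algorithm at each step, so the defaults here are declared choices:

* **Feature sub-clustering** — hierarchical, correlation distance
  (1 − Pearson), average linkage: the standard recipe for co-expression
  blocks. Seeded k-means is available as an option. Degenerate maxclust
  cuts that return fewer than k clusters are repaired by promoting the
  farthest member of the largest cluster to a singleton.
* **Within-sub-cluster sample split** — Ward on the Euclidean distance of
  the member-feature submatrix, cut at 2. The 0/1 orientation (higher
  mean → 1) is arbitrary but fixed for reproducibility; downstream
  clustering is label-symmetric.
* **Consensus resampling** — default 1 000 reps at sample fraction 0.8
  (the conventional consensus-clustering defaults; the bundled search and
  tests use fewer reps, see *Problem sizes*). Per rep, one
  average-linkage tree is built on the subsampled NA-tolerant Hamming
  distance and cut at every candidate k; sharing the tree across k keeps
  the per-k consensus matrices mutually consistent and makes grid
  evaluation tractable. Consensus(i,j) is the co-clustering count over
  the co-sampling count; never co-sampled pairs get 0 with a warning.
* **Final label cut** — the tree on 1 − consensus is cut with **Ward**
  linkage rather than average linkage. This is deliberate: average-
  linkage cuts of an unstructured consensus matrix shed near-singleton
  clusters, and the log-rank chi-square approximation is severely
  anti-conservative for such group sizes (measured ~30 % type-I error at
  nominal 0.05 for sizes [114, 2, 2, 1, 1]). Ward's balance preference
  keeps null subgroups near-equal in size, restoring the nominal level,
  and leaves recovery of genuinely separated subgroups unchanged.
  Near-singleton subgroups are also biologically uninteresting as
  subtypes.

## Choosing the number of subgroups

For each k the empirical CDF of the off-diagonal consensus entries is
integrated; the chosen k is the largest whose relative area increase over
k − 1 exceeds 0.05 (for k = 2 the area itself is used). On unstructured
data this curve decays too slowly to ever certify stability, so a guard
rejects the choice when more than 40 % of the consensus entries at the
candidate k lie strictly between 0.1 and 0.9 (measured: 0.44–0.91
ambiguous on random binary matrices vs ≤ 0.14 on planted structure at the
true k) and returns the minimum k with an instability warning.

## Survival-guided selection

Survival is compared across subgroups with the k-sample log-rank test
(lifelines; hypergeometric tie correction, χ² with k − 1 df), and a grid
combination is "significant" at p < 0.05. No multiple-testing correction
is applied across grid points by default, matching the selection-by-
recurrence design (a Benjamini–Hochberg flag exists for principled use).
Recurrence is computed per platform independently — the modal sub-cluster
count among significant points, ties broken toward the smaller count.
Sub-clusterings and indicator rows are cached per (platform, k), so the
grid reuses them. With a budget smaller than the full grid, combinations
are drawn uniformly without replacement with the run's seed.

The LOOCV classifier is nearest-centroid on the indicator matrix under
the NA-tolerant mean absolute difference — the minimal classifier
consistent with centroid-style subgroup calling; samples in singleton
subgroups are skipped with the denominator adjusted.

## Synthetic data

The generator emulates exactly the structure the model assumes: Gaussian
feature blocks with a shared per-(block, sample) latent (SD 0.8 by
default) for within-block correlation, plus a mean shift of
*effect* × noise-SD for samples in the block's *active* subgroups.
Activation patterns cycle through singleton subgroups and then adjacent
pairs, so the stacked bits identify every subgroup. Platform value scales
mimic the real formats — CNV is emitted as per-sample *segment records*
(so the interval-overlap code path is exercised), methylation betas are a
logistic map of the latent (exactly invertible by logit, used by the
moment tests), mRNA/miRNA are 2^latent abundances. Survival is
exponential with per-subgroup log-hazard offsets (default: a 3-fold
hazard ratio between extreme subgroups) and independent exponential
censoring tuned to an expected 30 % censored fraction. Mutations are
Bernoulli with baseline rate 0.05 and subgroup-enriched genes at 0.45;
clinical covariates have subgroup-biased level frequencies.

Defaults (250 samples, 5 equal subgroups, 2-noise-SD block effects; CNV
in log₂-ratio units with the same effect-to-noise ratio) give a clearly
but not trivially separable study: individual block splits misassign
10–25 % of samples at 2 SD, and it is the consensus over ~28 indicator
rows that drives the final ARI above 0.95. At 3 SD individual splits are
already ≥ 95 % correct.

What the generator does **not** model: beta-mixture methylation
marginals, platform-specific noise families, realistic LD/segment-length
distributions, missing-at-random patterns other than undetected features,
or real LIHC effect sizes. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated block
model, not performance on any particular real cohort.

## Problem sizes used in bundled runs

The test suite and the acceptance script scale the expensive stages to
desk size as the package's own evaluation design: synthetic platforms of
60–300 features, consensus with 100 reps for final calls (10–30 inside
grid searches), grid budgets of 1–50 combinations, recovery over 5 seeds,
and null calibration over 72 independent studies of 300 samples with one
grid point each. One grid point per null study is essential: points
evaluated within one study share its survival draw and are strongly
positively correlated (measured design effect ≈ 3.7), which would
invalidate a binomial check of the significant fraction. 300 samples per
null study because the log-rank χ² approximation is still mildly
anti-conservative at 200 samples with Ward-cut group-size spread
(measured 0.071 at n = 200 vs 0.058 at n = 300 over independent points).

## Reference cohort tables

`coca.reference_data` ships the printed subgroup × covariate counts and
TP53/CTNNB1 mutation tallies of a published five-subgroup TCGA HCC cohort
(~256 samples). They are inputs, not outputs: the validation recomputes
the cohort's quoted summary percentages (70 % / 24 % TP53, 43 % / 20 %
CTNNB1, 60 % / 32 % female, 57 % / 30 % alcohol, 24 % / 54 % high AFP)
from these counts through the package's own proportion and association
utilities. The exact test behind the cohort's printed p-values is not
recorded, so p-values are validated qualitatively (significant at 0.05),
not numerically.

## Known limitations

* The real cohort's selections (13/15/6/9 sub-clusters, five subgroups,
  81.3 % LOOCV) require the original TCGA LIHC download and are not
  reproducible from this repository; the synthetic recovery properties
  are the substitute.
* Fisher's exact test is exact only for 2×2 tables; larger tables use a
  seeded Monte Carlo permutation of the χ² statistic.
* The exponential censoring rate is matched in expectation via the mean
  event rate, so the realized censored fraction drifts slightly when
  hazards differ strongly across subgroups.
* Gene–segment overlap is computed by per-chromosome scan, adequate for
  cohort-scale SEG files but not optimized for million-segment inputs.
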