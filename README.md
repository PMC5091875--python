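# coca — survival-guided cluster-of-clusters multi-omics integration

`coca` implements a "cluster of clusters" (COCA-style) pipeline for
molecular subtyping of cancer cohorts from TCGA-style level-3 flat files:
copy-number segments, DNA-methylation beta values, mRNA and miRNA
expression, somatic mutations and clinical follow-up. It is aimed at
computational biologists who want a tested, reproducible implementation of
the approach — originally developed for hepatocellular carcinoma, where
integrating four platforms yields subgroups with distinct survival — that
also runs end-to-end on bundled synthetic data with known ground truth.

## The method

Each platform is first reduced to its most variable features (gene-level
copy-number scores clipped to ±2 with SD > 0.2; the 10 000 most variable
CpG sites; the 6 000 most variable genes after log₂ with a −26 floor; the
80 most variable miRNAs after log₂ RPM with a 0 floor). Integration then
works row by row:

1. **Feature sub-clustering.** The features of platform *p* are divided
   into *k_p* sub-clusters (hierarchical, 1 − Pearson distance, average
   linkage).
2. **Binary indicators.** Each sub-cluster's member features split the
   samples into two groups (Ward 2-cut). If either group has fewer than
   10 samples the row becomes all-NA; otherwise the higher-mean group is
   coded 1, the other 0.
3. **Assembly.** The Σ*k_p* indicator rows form one {0, 1, NA} matrix
   over the common samples.
4. **Consensus clustering.** Samples are clustered on an NA-tolerant
   Hamming distance with resampling (80 % subsamples, co-clustering
   frequencies); the subgroup count is chosen where the consensus-CDF
   delta-area curve flattens.
5. **Survival-guided selection.** Steps 1–4 are repeated over a grid of
   per-platform sub-cluster counts (CNV 2–15, mRNA 2–15, miRNA 2–7,
   methylation 2–15; subgroups 2–7). Combinations whose subgroups differ
   significantly in survival (k-sample log-rank, p < 0.05) are kept, and
   the most recurrent count per platform wins.

Downstream utilities characterize the called subgroups: Fisher/chi-square
contingency tests against clinical covariates and mutations, subgroup
proportion summaries, leave-one-out nearest-centroid accuracy, one-vs-rest
ROC AUC biomarker ranking (AUC = U/(n₁n₂)), and rank-sum signature tables
with Benjamini–Hochberg correction.

## Worked example

```python
import coca
from sklearn.metrics import adjusted_rand_score

# simulate a 250-sample study with five planted subgroups
dataset = coca.simulate_multiomics(coca.SyntheticConfig(seed=1))
platforms = dataset.preprocessed_platforms()

# call subgroups at the generator's per-platform sub-cluster counts
result = coca.finalize_subgroups(
    platforms, {"cnv": 5, "mrna": 10, "mirna": 5, "meth": 8}, seed=1, reps=100
)
ari = adjusted_rand_score(dataset.true_labels,
                          result.final_labels.reindex(dataset.true_labels.index))
print(f"chosen subgroup count: {result.final_k}")
print(f"adjusted Rand index vs truth: {ari:.3f}")

res = coca.logrank_test(dataset.clinical, result.final_labels)
print(f"log-rank chi2 = {res.statistic:.1f} (df={res.df}), p = {res.p_value:.2e}")
```

prints

```
chosen subgroup count: 5
adjusted Rand index vs truth: 0.970
log-rank chi2 = 32.0 (df=4), p = 1.96e-06
```

The delta-area rule picks five subgroups, they match the planted labels
almost perfectly (ARI 0.97), and the called subgroups separate survival
(the generator plants a 3-fold hazard ratio between the extreme
subgroups).

The same stages are available from the shell:

```sh
coca simulate --seed 1 --out-dir data/
coca preprocess --platform mrna --in data/mrna.tsv --out mrna_prep.tsv
coca search --data-dir data/ --budget 50 --seed 1 --out search.tsv
coca finalize --data-dir data/ --counts 5,10,5,8 --out labels.tsv
```

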