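# Methods

## Data model and preprocessing

Expression matrices are genes × samples on a log2-intensity scale with
Entrez Gene row identifiers and per-sample class labels
(cancer/normal/unknown); a `batch_id` names the source dataset so that
per-dataset operations have a defined boundary. Readers reject duplicate
identifiers, non-numeric cells and missing values outright — the pipeline
performs no imputation, matching the microarray sources it emulates.
Probeset-level matrices are collapsed to genes by keeping, for each gene,
the probeset with the largest **mean** expression across samples. This is a
whole-probeset choice: taking per-sample maxima would stitch a synthetic
row from different probesets and destroy row provenance. Mean-centering is
per gene within a dataset (the matrix is the batch boundary); it removes
additive batch location differences and preserves within-gene sample
contrasts exactly.

## SAM

The two-class unpaired statistic is d = r/(s + s0), with r the cancer-minus-
normal mean difference and s the pooled standard error
√((1/n₁+1/n₂)·SS/(n₁+n₂−2)). The fudge factor s0 is chosen from {0} ∪
{percentiles 0,5,…,100 of s} to minimize the coefficient of variation of
window-wise median absolute deviations of d, with genes windowed by
quantiles of s (window count = min(100, G/10) so each window holds ≈10
genes at small G). The permutation null shuffles class labels (simple
random permutations; 1000 by default); expected order statistics d̄₍ᵢ₎ are
the mean over permutations of the i-th order statistic, ties in the
observed order broken by original index for determinism.

Calling at a threshold Δ: scanning upward from the first index where
d₍ᵢ₎ ≥ d̄₍ᵢ₎, cuthi is the smallest d₍ᵢ₎ with d₍ᵢ₎ − d̄₍ᵢ₎ ≥ Δ (cutlo
symmetric); genes beyond the cuts are called. FDR(Δ) = π₀ · median over
permutations of the count of permuted statistics beyond the cuts, divided
by the observed call count. π₀ is the SAM-manual convention — the fraction
of observed d inside the central quartiles of the permuted distribution
over 0.5 — capped at 1 and configurable to 1.0 (the original convention).
Δ is scanned over 200 evenly spaced values from 0 to max|d₍ᵢ₎ − d̄₍ᵢ₎| and
the smallest value with FDR ≤ the target is used; an unreachable target
yields an empty call set, not an error. The optional fold-change gate
requires |mean difference| ≥ log2(threshold) on the statistic's input
values and is applied to the final call sets (the FDR table itself is
ungated, as in the reference tool).

The quantitative variant rank-transforms each gene and the continuous
response (average ranks, SD-scaled) so the per-gene statistic is exactly
Spearman's ρ with the response; s0 = 0 because the statistic is already
scale-free. Permutations shuffle the response.

### DEG selection across cohorts

The tumor/normal dataset (both classes, matched design) and the
control-only dataset are intersected on genes and mean-centered
independently; SAM then compares the centered tumor-cohort cancer samples
against the centered controls. Centering a class-balanced dataset moves
half of the cancer/normal difference into the normal samples' residuals, so
the apparent effect in this comparison is half the within-dataset effect;
the permutation test is unaffected, but a fold-change gate computed on
centered values would implicitly demand 4-fold real changes. Both
fold-change gates (cross-dataset and within the matched dataset) are
therefore computed on the **original** group means. Signs follow the
within-dataset cancer-minus-normal direction.

## Meta-radiomics

Features with exactly constant values (tested as zero range, which is
immune to floating-point noise in the standard deviation) are removed; the
rest are z-scored per feature. The clustered objects are the **features**,
as points in sample space — the table orientation is samples × features, so
this is stated explicitly. K-means uses seeded k-means++ initialization
(D²-sampling) by default with `init='random'` available; uniform random
point initialization seeds all of K well-separated clusters with
probability K!/K^K (≈0.2% at K = 8) per restart and routinely lands in
merged-cluster optima even with 10 restarts, whereas k-means++ recovers the
planted K reliably. Lloyd iterations assert non-increasing inertia; empty
clusters are repaired by reseeding from the farthest point.

K is selected over [2, 100] (capped below the feature count) by the best
mean rank of silhouette (descending) and Davies–Bouldin (ascending), ties
to the smaller K. Inertia is reported for elbow inspection but not ranked —
it is monotone in K and has no intrinsic optimum. The homogeneity score of
a cluster is the mean pairwise Spearman correlation of its members
(rank-based, hence identical on raw and standardized values); singletons
score 1 by convention (configurable to `exclude`). Clusters with h > 0.75
are represented by the member minimizing squared Euclidean distance to the
centroid in standardized space; exact ties are broken by a seeded uniform
choice. PCA projection of the feature points is provided for plotting the
clusters as coordinate tables.

## Dual screens and the signature

The Spearman screen tests each DEG against every radiomic feature and
applies Benjamini–Hochberg **within the gene's feature family** (the ~707
features of that gene), pair-significant at q ≤ 0.05. Spearman/Pearson
p-values use the two-sided t-approximation t = ρ√((n−2)/(1−ρ²)) for all n
(an exact permutation p is available for n ≤ 9). The SAM screen runs one
quantitative SAM per feature with the feature as response. A gene enters
the transcriptomic signature when it is a DEG and has at least one
significant feature association under **each** method (per-gene
intersection; a stricter per-pair mode — the same (gene, feature) pair
significant under both — is available via `granularity='pair'`).

## p-metaomics

Predictors (signature genes) are z-scored with the transform stored in the
model; λ runs over 100 log-spaced values from λmax = max|X'y|/n down to
10⁻⁴·λmax. LOOCV held-out predictions pick the λ minimizing cross-validated
MSE, ties to the larger (sparser) λ; the final model is refit on all
samples at that λ. R² is **in-sample** on the refit model (cross-validated
error is reported separately as CV-NRMSE); NRMSE is RMSE normalized by the
range of the observed values. Models must clear R² > 0.70 and show at least
one significant Spearman correlation (BH within the model's family at 5%)
between their prediction and the signature genes — all signature genes are
tested, not only the nonzero support. Application to an external cohort
z-scores genes **within that cohort** before evaluating the standardized-
scale linear form; this neutralizes batch location/scale without needing
the training transform to be meaningful there. Only nonzero-coefficient
genes are required to be present; missing support genes raise by default or
drop the affected model under `drop_incomplete_models`.

## Validation

The linear SVM uses fixed C = 1 with per-gene z-scoring within each cohort
(kept fixed for determinism; the studies this emulates report the linear
kernel as best, so only linear is implemented). Hierarchical clustering
defaults to Euclidean complete linkage. BHI averages, over clusters with at
least two members, the fraction of ordered within-cluster pairs sharing a
biological class; singleton clusters are skipped (their pair set is empty).
BSI reclusters after deleting each condition column in turn and averages
the relative overlap of full-data and reduced-data co-cluster sets over
ordered same-class pairs, then over deletions and classes. Both indices are
verified against brute-force pair-counting oracles in the test suite.

## Synthetic study generator

The generator is a pure function of (config, seed) and defines the study
conditions everything is tested under. Gene baselines are N(7, 1.5²) log2
units with i.i.d. N(0, 0.5²) per-sample noise; DEGs (100 of 1000 genes by
default) receive a class shift of magnitude U(1.5, 2.5) log2 with random
sign; each cohort gets an independent per-gene batch offset N(0, 0.3²);
matched cohorts share a N(0, 0.2²) subject intercept between a cancer
sample and its paired normal. The default study mirrors the scale of the
multi-cohort design it emulates at desk cost: a 24-sample tumor-only
cohort that also carries the radiomic table, a 40+40 matched tumor/normal
cohort, a 40-sample control cohort, and a 30+30 external validation
cohort over 1000 genes.

The radiomic table has 15 latent prototypes × 46 member features + 17
constant features = 707 columns. Members are a·z + b + N(0, 0.3²) with
a ~ U(0.5, 2) positive, so after z-scoring a cluster's members concentrate
around its prototype direction. Five prototypes are gene-driven: z =
√R²·ẑ + √(1−R²)·ε with ẑ the standardized weighted sum (|w| ~ U(0.5, 2))
of an 8-gene support and R²_true = 0.9.

Driver supports are planted as **co-expressed modules**: the 8 support
genes share a per-sample latent activity factor with signed loadings at
within-module correlation 0.8. This is a deliberate design choice. With
fully independent support genes the squared gene–prototype correlations
must sum to R²_true, so the average |ρ| cannot exceed √(0.9/8) ≈ 0.33 — at
24 samples no per-gene screen can recover such a support even in principle,
and the recovery properties the pipeline is tested on would be vacuous.
Differential genes that jointly drive a phenotype are co-regulated pathway
members in real cohorts, so module covariance is also the more realistic
model; with it each support gene correlates ≈0.85 with its prototype. The
generator does **not** attempt realistic radiomic feature marginals, gene-
length or GC effects, probe-level noise, or dropout — only the correlation
and effect structure the pipeline consumes — so passing tests certify the
statistical machinery, not robustness to every artifact of real arrays.

## Problem sizes and numerical choices

Default problem sizes (1000 genes, 707 features, 100 permutations in unit
tests and 1000 in the pipeline default, 5-seed end-to-end replication) were
chosen so the full suite replicates the funnel behavior of a realistic
study while remaining a desk-scale computation. Permutation machinery is
seed-deterministic; all stage seeds derive from one master seed by hashing
the stage name, so any stage reruns in isolation. Floating-point text
serialization uses 17 significant digits so round trips are exact to
1e-12. Degenerate inputs (constant genes/features/responses, empty
intersections, unreachable FDR targets, missing model genes) either raise
a named error or degrade to an explicitly logged empty result, as
documented per function.

## Known limitations

- Only the two-class unpaired and quantitative SAM modes exist (no paired,
  survival or multiclass variants).
- The cross-dataset DEG comparison assumes the tumor dataset is roughly
  class-balanced; strongly unbalanced designs change how much class signal
  survives mean-centering.
- BHI/BSI treat every object as annotated; partially annotated universes
  are not supported.
- The reverse mapping (predicting expression from radiomics) is out of
  scope, as are enrichment analysis and any image-level feature extraction:
  the package consumes feature tables, it does not compute them.
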