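# Methods

## The problem

Infinium 450K-style methylation arrays report a beta value per CpG locus and
sample — the ratio of methylated to total signal, in [0, 1] — for hundreds of
thousands of loci but typically only tens to hundreds of samples per cohort
(feature:sample ratios on the order of 1,000:1). Differentially methylated
loci (DML) separate tumor from normal samples, but any single feature-selection
method run in this regime is unstable: small perturbations of the cohort change
the selected set substantially, which undermines downstream biological
validation. The package implements a hybrid ensemble that combines *instance
perturbation* (repeated stratified cross-validation splits) with *function
diversity* (three heterogeneous selectors) and keeps only loci that recur
across perturbations.

## The pipeline

One iteration of the ensemble:

1. Split the samples into k stratified folds (default k = 10).
2. For each fold, the held-in samples train each base selector i, producing a
   nonnegative per-locus weight vector f_i, max-normalized to [0, 1]. A linear
   SVM trained on the loci that selector supports (weight ≥ τ) is scored on the
   held-out fold, giving acc_i.
3. The rankings are combined per locus by the accuracy-weighted sum
   f_j = Σ_i acc_i · f_ij, and loci with f_j < τ are dropped (τ = 0.01;
   the boundary value is kept).
4. The per-fold survivor sets are unioned over the k folds, summing a
   surviving locus's aggregated weights across the folds that kept it.

T iterations (default 10), each with freshly drawn folds, produce sets
F_1 … F_T; the bagging consensus keeps loci present in at least c of them
(default c = 5; the source pseudocode's "filters out loci which appears less
than five times" is read literally as keep-if-count ≥ 5, and c is exposed for
users who prefer the stricter reading). The final weight of a kept locus is
its mean iteration weight.

Per-iteration fold assignment is reseeded deterministically from the master
seed and the iteration index; the Monte Carlo selector is reseeded per
(iteration, fold, selector). A whole run is therefore reproducible from one
integer.

## Base selectors

**Elastic net.** Penalized least squares on standardized features with labels
coded {0, 1}, no intercept:

    argmin_w  Σ_i (y_i − wᵀx_i)² + λ [ α ||w||₁ + (1 − α) ||w||₂² ]

The penalty enters exactly in this parameterization (no 1/m or 1/2 factors);
the coordinate-descent solver's scaling is mapped accordingly, and the α = 0
(ridge) limit is solved in closed form as (XᵀX + λI)⁻¹Xᵀy, which doubles as
the test oracle. Ranking weight = |w_j|. λ = "auto" (the default) runs 5-fold
cross-validation on the training split only, over a 20-point log grid from the
null threshold λ_max = 2·max_j|X_jᵀy|/α down to λ_max/100 (the conventional
floor when p ≫ n), choosing the largest λ within one standard error of the
minimum validation MSE. Standardization is computed once on the training split
before the internal CV; this mild shortcut affects only the internal λ choice,
never touches the held-out fold, and saves a large constant factor. The
squared-loss form is used as the primary objective; a logistic-loss variant is
available behind the `logistic` flag. Default α = 0.5.

**Information gain.** Each locus's beta values are discretized into
`ig_bins` = 10 equal-width bins on [0, 1] (bounded support makes fixed edges
reproducible), and IG = H(class) − H(class | bin) is computed with base-2 logs
and the 0·log 0 = 0 convention. Because the plug-in estimate is positively
biased at small n, the selector screens loci by the G-statistic
2N·ln2·IG, asymptotically χ² with (occupied bins − 1) degrees of freedom,
and zeroes loci not significant under Benjamini–Hochberg control. The default
level is 0.01 rather than the conventional 0.05: the ensemble unions the
screen's rejections over ~10 highly correlated folds per iteration, which
inflates the false-discovery contribution of the unioned set several-fold, and
dataset-level false rejections recur in every iteration, so the bagging
consensus cannot remove them. `ig_fdr=None` gives the raw estimate (used by
the entropy oracles in the tests).

**Monte Carlo random subspaces.** `mc_subspaces` = 300 random subspaces of
`mc_subspace_size` = min(p, ⌈√p⌉·5) loci are drawn; per subspace,
`mc_trees` = 1 decision tree is grown on a bootstrap resample, and every locus
in the subspace accumulates (out-of-bag balanced accuracy) × (its
impurity-decrease share). Relative importance = accumulated score / number of
containing subspaces. A second pass with permuted labels yields a null
importance distribution; relative importances not exceeding its maximum
(`mc_null_quantile` = 1.0, a shadow-feature-style cutoff) are zeroed. This
construction is the package's own concrete realization of the
subspace-sampling selector family; its internals are deliberately simple and
fully seeded.

All three selectors return |weights| max-normalized to [0, 1]. This common
scale is what makes the accuracy-weighted sum and the fixed threshold τ = 0.01
meaningful: the selectors' native scales (regression coefficients, bits,
importance shares) are not comparable. Equally important, each selector is
*sparse* — loci it does not support get weight exactly 0. A dense scorer would
defeat the threshold: for example, raw plug-in information gain gives null
loci ~10% of the maximum weight at n ≈ 50, so τ = 0.01 would retain
essentially every locus and the bagging consensus would never prune.

## Stability and performance measures

Selection stability is the mean pairwise Jaccard index over the signatures
obtained under instance perturbation:

    S_tot = 2 Σ_{i<j} |f_i ∩ f_j| / |f_i ∪ f_j|  /  (k(k−1))

Two empty signatures count as identical (Jaccard 1), empty vs non-empty as 0,
so a deterministic pipeline always scores 1. The stability experiment draws
`n_subsamples` stratified 90%-without-replacement subsamples, runs each method
on each subsample, truncates its ranking to each requested signature size
(ties broken by locus id), and reports S_tot per (method, size) plus the AUC
of a linear SVM trained on each signature and scored on the 10% held-out
complement. The 90% scheme mirrors the pipeline's own 10-fold-flavored
perturbation; it is the package's choice.

Classification metrics are the confusion-matrix suite with the tumor class
positive (TPR, FPR, ACC, precision, recall, F1; 0/0 conventions → 0) and an
exact pair-counting AUC (the Mann–Whitney probability, ties counted ½),
which is unambiguous under ties and directly oracle-checkable; the tests
cross-check it against trapezoidal ROC integration on tie-free inputs.

## Pan-cancer consensus and characterization

A locus is a pan-cancer DML (pDML) when it occurs in at least `min_cancers`
of the per-cancer sets (default 10, matching the 10-of-13 reference rule; the
boundary is inclusive). Per cancer, direction is called from the sign of
median(tumor) − median(normal), with an optional dead band δ (default 0).
Region annotation assigns promoter — the strand-aware window from 2,000 bp
upstream of a TSS through the TSS, both ends inclusive — with precedence over
gene body (any gene span), else intergenic; a locus in any gene's promoter
window is promoter regardless of other overlapping genes. Strand-awareness of
the upstream window is an interpretation choice (the convention only says
"upstream"); genes with unknown strand are treated as + with a logged
warning. Chromosome-level density is |DML on chromosome| / |array background
loci on chromosome|; chromosomes without background loci are reported as
undefined rather than zero. Cross-cancer similarity uses the Jaccard index of
DML sets with average-linkage agglomerative clustering on 1 − Jaccard (the
linkage choice is the package's; inputs are sorted lexicographically by name
so ties resolve deterministically), serialized as a merge table and a Newick
tree with ultrametric branch lengths.

## Preprocessing scope

Probe-type normalization and batch correction are assumed done upstream by
the standard external tools; `normalize_hook` is a pass-through slot. The
package's own preprocessing: loci with > 20% missing entries are dropped and
the remainder median-imputed per locus, class-agnostically (selectors need
complete matrices; the missingness policy is the package's own); minimal-
variance filtering keeps either the top-k most variable loci or those above a
variance cutoff, computed as unbiased sample variance over non-missing
entries without consulting labels, with lexicographic tie-breaking. No
default k is claimed as faithful to any particular array count.
SNP-overlapping loci are *flagged*, never silently removed: the flag survives
into the BED output's trailing column, and the CLI's `--drop-snp` lets users
choose stringency.

## Synthetic cohorts

`simulate_cohort` draws a baseline mean per locus from a trimodal mixture
(modes ≈ 0.1 / 0.5 / 0.9 with probabilities 0.4 / 0.2 / 0.4 and Gaussian
jitter 0.04), mimicking the multi-modal beta-value landscape of methylation
arrays, and samples both classes from a beta distribution parameterized by
(mean, concentration); concentration 20 gives a per-locus spread of roughly
0.06–0.11, a realistic array-level noise scale. Planted loci redraw their
baseline uniformly inside the interval where a ±effect_size shift stays in
(0.05, 0.95), so the nominal effect is realized exactly in expectation;
directions alternate hyper/hypo. Entries can be masked missing at a fixed
rate. Defaults (30+30 samples, 2,000 loci, 50 planted, effect 0.35) define
the standard recovery experiment; they represent a desk-scale cohort in the
same qualitative regime as real array studies — bounded multi-modal values,
p ≫ n, a small planted minority — while remaining runnable in minutes.

What the generator does *not* emulate: probe-type chemistry, spatial
correlation along the genome, batch structure (an additive-logit batch option
exists only as a stress test), cell-type composition, and realistic
linkage between loci (loci are independent given their means). Passing the
recovery experiments therefore shows the pipeline's machinery is correct and
calibrated under its own model assumptions, not that real-array effect sizes
or correlation structure would yield the same rates.

`simulate_pan_cancer` builds several cohorts over a common locus universe; a
configurable fraction of each cohort's planted loci comes from a shared pool
planted in every cancer (the ground-truth pDML candidates), the rest are
cancer-private and disjoint across cancers.

## Experiment sizes used by the test suite and acceptance script

- Recovery and null calibration: the generator defaults above, pipeline
  defaults (k = 10, T = 10, τ = 0.01, c = 5).
- Stability comparison: same cohort; 3 subsamples per replicate, 10
  replicates, signature size 50; the ensemble's ranking engine inside the
  experiment runs a trimmed configuration (k = 5, T = 1, 100 MC subspaces)
  since the experiment reranks from scratch once per subsample.
- Pan-cancer: 13 cohorts of 20+20 samples × 600 loci, 40 planted (half
  shared), effect 0.45, pipeline k = 5, T = 3, c = 2, pDML rule min 10.
- Determinism: two full runs on a 300–600-locus cohort, compared byte-wise.

These sizes are the package's own choices for routine verification; all are
plain parameters, so larger studies are a flag away.

## Numerical and degenerate-input conventions

- Threshold comparisons keep the boundary (f ≥ τ; count ≥ c; occurrence ≥ min).
- A selector whose support at τ is empty gets fold accuracy 0 and thus
  contributes nothing to the aggregate.
- An empty final consensus is a warning, not an error.
- Constant loci: variance 0, elastic-net weight 0 (standardized to a zero
  column), information gain 0, no tree split — all selectors agree on 0.
- Fold partition: per-class round-robin with a cumulative offset; fold sizes
  differ by ≤ 1 and per-fold class counts are within 1 of proportional.
  Classes smaller than k are allowed (absent from some folds) — required for
  odd cohort sizes; errors are reserved for k < 2, k > n, or an empty class.
- Beta draws are clipped to [1e-6, 1 − 1e-6] so generated values are strictly
  inside (0, 1).
- All derived seeds are folded through `numpy.random.SeedSequence` and kept
  below 2³¹.

## Known limitations

- The squared-loss elastic net treats binary labels as a regression target
  (as its objective is written); the logistic variant exists but is not the
  default and is not used by the headline experiments.
- The Monte Carlo selector's null cutoff (max of one permuted run) is a
  single-permutation bound; it is cheap and conservative but noisy for very
  small subspace counts.
- The accuracy weights acc_i are computed from each selector's own supported
  loci; when a selector supports nothing, its information is discarded
  entirely rather than backed off to a default ranking.
- Stability is measured only with the Jaccard index; size-corrected indices
  (e.g. Kuncheva) are out of scope.
- The pipeline addresses class imbalance only through stratification; the
  SVM's `balanced` class-weight mode exists behind a flag but is off by
  default.
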