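# Methods

## Problem and model

`crossomic` looks for *disease-associated multi-omic modules*: small sets
of features drawn from two or more omic layers (taxonomic relative
abundances `T`, pathway relative abundances `P`, fecal/serum metabolite
intensities `M`/`S`) that (i) co-vary with each other across samples and
(ii) jointly separate cases from controls. The working assumption is that
a real biological axis of variation — a sub-community of taxa, the
pathways they carry, the metabolites they produce — expresses itself as a
shared latent factor visible in several omics at once, and that features
loading on that factor shift together between disease states.

### Sparse generalized CCA with a label block

Given standardized blocks X_1 … X_J (samples × features) and a design
matrix C (c_jk ≥ 0, symmetric, zero diagonal), one component solves

    maximize   Σ_{j<k} c_jk · cov(X_j a_j, X_k a_k)
    subject to ‖a_j‖₂ = 1,  ‖a_j‖₀ ≤ keep_j ,

i.e. one sparse loading vector per block such that the latent variates
t_j = X_j a_j are maximally co-varying according to C (the identity /
"horst" covariance scheme). The binary phenotype enters as an extra
single-feature block: the 0/1 labels centered and scaled to unit SD, with
keep fixed at 1 and design weight 1 to every omic block. This biases the
variates toward directions that also separate the classes. Omic–omic
design weights default to `des = 1` (fully connected); `des = 0` couples
the omics only through the label.

The solver is block-coordinate ascent. For block j the inner target is
ω_j = Σ_k c_jk t_k; the raw direction u_j = X_jᵀ ω_j is soft-thresholded
at the (keep_j+1)-th largest |u_j| so exactly keep_j entries stay
non-zero, then renormalized. Convergence is declared when no loading
coordinate moves by more than `tol` (default 1e-6, `max_iter` 1000).
Further components are obtained by regression deflation
X_j ← X_j − t_j(t_jᵀX_j)/(t_jᵀt_j) per omic block; the label block is
never deflated, so every component is pulled toward the phenotype while
within-block variates stay orthogonal.

Numerical choices that matter:

- **Initialization.** Each component starts from each block's dominant
  right singular vector and first runs the ascent *without* the sparsity
  constraint to (loose, 1e-4) convergence; the sparse ascent continues
  from there. The dense warm start aligns the blocks with the globally
  dominant covariance direction before support selection — starting the
  sparse ascent directly from the SVD vectors visibly gets trapped in
  local optima on small blocks (the keep = 1 support then disagrees with
  exhaustive search on a noticeable fraction of random instances).
- **Two label starts.** The ascent is still a local method, so with a
  label block each component is fitted from both label orientations and
  the higher-criterion solution kept. This is deterministic and makes the
  result exactly invariant to swapping the case/control coding (the label
  column is additionally sign-canonicalized on entry).
- **Ties.** A tie at the sparsity boundary keeps the lowest feature index;
  a kept entry whose soft-thresholded magnitude is exactly zero receives a
  tiny positive value so the exact non-zero count holds. Ties have measure
  zero on continuous data.
- **Exact-count soft-thresholding** is the default ("keep" semantics);
  hard truncation is available via `sparsity_mode="hard"`.

### Consensus over subsamples

A single sGCCA fit is unstable on noisy compositional data, so the fit is
repeated on random subsamples: `nrep` runs (default 100), each using
(nfol−1)/nfol of the samples (default 4/5 = 80%) from label-stratified
fold partitions drawn round-robin. Stratification prevents class-empty
subsamples in small cohorts. Per run the first `ncomp` (default 5)
putative modules — the non-zero-loading feature sets — are recorded; a
feature pair co-occurring in any putative module of a run counts once for
that run. Pairs with co-occurrence frequency ≥ `edge` (default 0.8) form
the consensus network; its connected components of size ≥ 2 are the
consensus modules. Blocks are standardized on each subsample only, so no
held-out information leaks into a fit.

### Evaluation against size-matched nulls

Each consensus module is summarized by the first principal component of
its centered, unit-variance member submatrix. Because a PC's sign is
arbitrary, the module AUC is orientation-corrected: AUC = max(A, 1−A).
Cross-omic cohesion is the signed mean pairwise Spearman correlation
between member features from different omics (absolute-value variant via
`absolute_rho`). Both statistics are compared against `n_null` (default
100) random modules with the same per-omic feature counts. A module is
**disease-associated** when it spans ≥ 2 omics, its AUC exceeds
`auc_threshold` (default 0.7), and both its AUC and its cross-omic
correlation exceed the null means (a stricter 95th-percentile rule is
available via `exceedance_rule="p95"`). The module AUC is computed
in-sample on the full dataset; the honest out-of-sample counterpart is
the cross-validated random forest on module PC1 scores
(`evaluation.modules_pc_rf`), whose PCA loadings are fitted inside
training folds only.

Orientation correction makes the null AUC mean sit above 0.5 (≈ 0.53–0.65
depending on module size and n), which is why the exceedance comparison —
not a fixed 0.5 reference — is the right benchmark.

## Preprocessing

Per omic table, in order: total sum scaling to relative abundances (T/P)
or natural-log transform (M/S; pseudocount = half the column's minimum
positive value by default, configurable constant); removal of constant
features, features non-zero in < `min_prevalence` (default 15%) of
samples (for metabolites, prevalence is judged on the raw zeros, before
the pseudocount hides them), and — compositional omics only — features
with mean relative abundance < `min_mean_abundance` (default 5e-5);
removal of user-listed features (e.g. pathways outside the expected
taxonomic range); complete-linkage collapse of features with pairwise
|Spearman| > `collinearity_threshold` (default 0.99) to one seeded-random
representative. Complete linkage guarantees every within-cluster pair
exceeds the threshold. Filtered relative tables are *not* re-normalized
(the thresholds are defined on the original composition), so their rows
are subcompositions summing to ≤ 1. Spearman was chosen for the
collinearity step because it is rank-robust for abundance data; Pearson
is available. Standardization everywhere uses the sample SD (ddof = 1).

## Early-integration baseline

The reference classifier concatenates all omic tables and runs repeated
stratified cross-validation (default 5 folds × 10 repeats = 50
fold-models). Inside each training fold an all-relevant shadow-feature
selection runs first: each round appends a column-permuted copy of every
feature, fits a forest (100 trees), and scores a hit for every real
feature whose Gini importance beats the best shadow; after `n_iter`
(default 10) rounds, features in the upper binomial(n_iter, 0.5) tail at
α = 0.05 are selected (nothing confirmed ⇒ all features kept so the model
never sees an empty matrix). A 500-tree forest is then trained on the
selected features and scored on the held-out fold by AUC. Forest
hyperparameters are scikit-learn defaults; tuning is deliberately out of
scope. Per-feature significance uses label-permutation importance:
p = (1 + #{null importance ≥ observed}) / (n_perms + 1) over 100
label-permuted refits, BH-FDR across features. **Contributors** are
features selected in ≥ 50% of fold-models with q < 0.1.

## Cross-study comparison

Module pairs from different datasets are first narrowed to the feature
universe measured in both; pairs sharing ≥ 2 features get a two-sided
Fisher's exact test on the 2×2 membership table, BH-corrected across all
tested pairs (significant at q < 0.1; an enrichment-only alternative is a
flag). The genus co-occurrence statistic is the percentage of species
occurrences (over all modules and datasets) sharing a genus with ≥ 1
other species in their module; the null redraws each module's species
uniformly from its dataset's species universe, preserving module sizes,
with p = (1 + #{null ≥ observed})/(n_perm + 1). The genus is parsed as
the first whitespace/underscore token of the species name unless an
explicit genus map is supplied.

## Synthetic data generator

The generator plants known modules in otherwise unstructured tables so
every stage is testable without external data. Per module m the latent
factor is z_m = α_m·(label−½)·2 + ε, ε ~ N(0,1); each planted feature's
log-scale value is β·z_m + σ·N(0,1) plus a per-feature baseline mean
(N(0,1) across features, giving realistic abundance heterogeneity). Taxa
and pathway log-values are exponentiated into log-normal counts, mixed
with log-normal background features and closed to relative abundances
(compositional); metabolite log-intensities are exponentiated to raw
intensities so the pipeline's log-transform recovers them. Expected
consequences used as oracles: two planted features' log-scale correlation
is β²/(β²+σ²) when α = 0; the planted-module PC1 AUC grows monotonically
with α; α = 0 plants a correlated but label-independent (null) module.

Default conditions — 200 samples; 100 T, 100 P and 60 M features; one
planted (5, 5, 5) module with α = 1.5, β = 1, σ = 0.7 — are the package's
standard benchmark: a clearly detectable but noisy effect (planted
feature pairs correlate at ≈ 0.67, below the collinearity cutoff) in
tables wide enough that keep = 10 per omic must reject ~10× more
background than signal features. Balanced classes, no batch structure, no
sequencing-depth variation, and (by default) no zero-inflation — a
`dropout` rate adds zeros to exercise the prevalence filter. Passing the
benchmark therefore shows the machinery recovers a planted shared factor
under compositional closure and log-normal noise; it does not certify
performance under real cohorts' confounding, uneven depth, or
heavy-tailed sparsity.

## Determinism and seeds

One master seed spawns independent child seeds per stage (preprocessing,
subsampling, null draws, baseline), so e.g. changing `n_null` cannot
perturb the subsampling stream. Two runs with the same seed and inputs
produce byte-identical module tables.

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `keep` | 10 per omic | features retained per omic per component (heuristic default; tune per dataset) |
| `des` | 1.0 | omic–omic design weight (label links are always 1) |
| `nrep` | 100 | total subsample sGCCA runs |
| `nfol` | 5 | folds per partition ⇒ subsample fraction (nfol−1)/nfol |
| `ncomp` | 5 | components (putative modules) per run |
| `edge` | 0.8 | co-occurrence frequency needed for a consensus edge |
| `auc_threshold` | 0.7 | module PC1 AUC needed for classification |
| `n_null` | 100 | random size-matched modules per evaluation |
| `min_prevalence` | 0.15 | minimum non-zero fraction |
| `min_mean_abundance` | 5e-5 | minimum mean relative abundance (T/P) |
| `collinearity_threshold` | 0.99 | \|Spearman\| above which features collapse |
| `tol`, `max_iter` | 1e-6, 1000 | sGCCA convergence controls |

## Known limitations

- Binary phenotypes only; no covariate adjustment, batch correction or
  imputation.
- Connected components are a deliberately simple community notion; one
  spurious high-frequency edge can merge two otherwise distinct modules.
- The in-sample module AUC is optimistically biased by construction; use
  `modules_pc_rf` for an out-of-sample estimate.
- Whether "iterations" in the subsampling protocol counts partitions or
  runs is ambiguous in the field; here `nrep` counts total runs, the
  alternative is `nrep × nfol` runs via more partitions.
- The mean cross-omic Spearman is signed by default; modules with
  balanced positive and negative couplings can cancel toward zero (use
  `absolute_rho=True` when that pattern is expected).
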