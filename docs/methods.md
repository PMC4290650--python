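# Methods

## Problem setting

Given a normalized gene-expression matrix (samples × genes, log-scale
intensities), a per-sample compound annotation, and a binary pathology
occurrence matrix Φ (samples × findings, φᵢⱼ = 1 iff finding *Fⱼ* was
observed histopathologically in sample *i*), the package predicts, for a
new expression profile, the likelihood that each finding will present.
Findings are organ-qualified terms (`liver:Necrosis`,
`kidney:Cast, hyaline`); liver and kidney are the supported organs. The
pipeline consumes already-normalized matrices: probe-level processing and
array normalization are upstream concerns, missing values are rejected
rather than imputed, and the expression scale is taken as given.

## Individual pathology models

**Signature selection.** Per finding, genes are ranked by a two-sided
two-sample t-test between case and control training samples and the top
`signature_fraction` (default 0.05) with smallest p-values are kept, with
count `ceil(fraction × n_genes)`. Welch's unequal-variance statistic is
the default since case and control groups are usually very different in
size and spread; a pooled-variance variant is available via `equal_var`.
A gene with no variance in either group and equal means is assigned
p = 1 (no evidence). Ties in p are broken toward larger |t|, then
lexicographic gene id, making selection deterministic and invariant to
input column order. No multiple-testing correction is applied — the
selection is a fixed-size ranking, not an inference. The signature is
always recomputed on the training samples of the current fold.

**Jackknife KNN ensemble.** Case/control imbalance is handled by
resampling the majority class: each of `n_submodels` (default 25)
jackknife samples keeps *every* confirmed case and draws
`control_subset_size` controls without replacement (default
`"balanced"`, i.e. as many controls as cases — classical undersampling).
Each sub-model is a KNN classifier (`knn_k` default 5, odd to avoid
50/50 votes) on Euclidean distance over the signature genes; no further
feature scaling is applied because inputs are already normalized. A
sub-model's output is the *fraction* of case labels among the k nearest
training points — a genuine [0, 1] score rather than a hard vote — and
the pathology prediction score (PPS) is the arithmetic mean over
sub-models. Distance ties at the k-th neighbor are resolved toward the
lexicographically lower sample id, so scoring is reproducible. When a
balanced jackknife sample is smaller than `knn_k` (a 2-case finding
yields 4 training points), k is capped at the training-set size instead
of refusing to train: rare findings are precisely where the method is
needed. Findings with fewer than 2 cases or 2 controls (the t-test
minimum) are reported untrainable, and the evaluation layer skips them
for that fold with a logged warning.

The values of `n_submodels`, `knn_k` and the subset size are package
defaults chosen for stability at desk scale, not reconstructions of any
particular study; all are configurable through `StudyConfig`.

**Randomness.** One master seed per study. Per-fold, per-finding,
per-submodel seeds are derived through `numpy.random.SeedSequence` spawn
keys, so serial and parallel execution, and repeated runs, agree exactly.

## Pathology relationships and integration

Pairwise co-occurrence is the Jaccard coefficient of occurrence columns,
S(Fᵢ,Fⱼ) = N₁₁/(N₀₁+N₁₀+N₁₁); co-absence never enters, so padding the
cohort with all-negative samples changes nothing. The empty-union case
0/0 is defined as 0; the diagonal is fixed at 1 even for a finding with
no cases in the current training fold, so that finding degrades to its
own PPS instead of being zeroed. S is row-normalized into integration
weights. The default `l2` scheme divides each row by its Euclidean norm,
N(Fᵢ,Fⱼ) = S(Fᵢ,Fⱼ)/√(Σₘ S(Fᵢ,Fₘ)²), giving unit-norm rows and a
dominant self-weight; a `sum_sq` scheme (divide by Σ S², no root) is
kept for sensitivity analysis because the two denominators are easy to
confuse in print. N is deliberately *not* symmetric — normalization is
row-wise.

The integrative prediction score is the linear pass
IPS_Fᵢ(s) = Σₘ N(Fᵢ,Fₘ)·M_Fₘ(s), i.e. IPS(s) = N·M(s), summing over all
findings including Fᵢ itself. IPS is not clipped to [0, 1]; thresholds
are tuned on the IPS scale, so the unbounded range is harmless. A finding
is called present when its score is strictly greater than its threshold
(boundary equality → absent).

## Evaluation protocol

Folds are random balanced partitions of the *drugs* (sizes differ by at
most one); all samples of a compound share its fold. Within each fold,
signature selection, model fitting, and similarity extraction all use the
training drugs only — the refit artifacts (per-fold signatures,
similarity matrices, thresholds) are retained in the report so leakage
audits can verify they differ across folds. `cv_folds` defaults to 5.

Thresholds maximize the geometric mean √(sensitivity × specificity), the
usual operating point for imbalanced data. Candidates are midpoints
between consecutive distinct scores plus one candidate below the minimum
and one above the maximum; gmean ties break toward the lowest threshold
(favoring sensitivity). Thresholds are tuned on training-fold scores:
tuning on test predictions would leak. Training-fold scores do include
each training sample's own contribution to its neighborhoods (cases are
in every jackknife sample), which biases training scores optimistic; this
affects only the operating point, never the held-out AUC. Sensitivity and
specificity are pooled over test folds with each fold's own threshold
(micro-average); a per-fold breakdown is retained for macro-averaging.
AUC is the rank-based Mann–Whitney statistic with half credit for ties,
computed on pooled held-out scores. ROC curves are emitted as (FPR, TPR)
coordinate tables rather than figures.

When the training-fold similarity matrix is the identity (findings never
co-occur), IPS equals PPS exactly — score vectors, thresholds and all
metrics — which serves as an end-to-end consistency check.

## Synthetic data

The generator emulates what the pipeline relies on, not array physics:
drug-grouped samples, rare findings, correlated co-occurrence, and
planted signatures. Each drug activates a subset of latent toxicity
mechanisms (Bernoulli, `activation_prob` 0.3 unless an explicit
activation matrix is given); a sample's mechanism activity is its drug's
activation plus Gaussian noise (`mechanism_noise_sd` 0.5); a finding's
latent score is its loading-weighted activity, and it occurs above the
empirical quantile matching `prevalence_target` — calibrating from the
realized latent distribution honors the prevalence regardless of loading
scale. Findings sharing mechanisms co-occur; each occurring finding adds
`effect_size` (in units of `background_noise_sd`) to its block of
`signature_size` genes, disjoint across findings by default with a
configurable overlap fraction for shared-pathway genes. Background
expression is i.i.d. Gaussian.

Defaults are desk-scale: 20 drugs × 10 samples, 400 genes, 6 findings on
3 mechanisms, prevalence 0.15, effect 1.5 sd, signatures of 20 genes.
What the generator does *not* emulate: probe-level artifacts, batch
effects, dose/time covariates, organ-specific expression (a finding's
signature is planted in every occurring sample regardless of the
profiled organ), and non-Gaussian intensity distributions. Tests passing
on this generator show the pipeline's logic and its imbalance/integration
behavior are correct; they are not a claim about absolute performance on
real array data.

`imbalanced_codependent_design` captures the regime where integration
matters: a rare finding (prevalence 2%, about 1:49 imbalance, effect
0.5 sd) nested inside two strong findings (prevalence 4%, effect 2 sd,
Jaccard 0.5 with the rare one) over a genome-scale universe of 5000
genes, plus two background findings on a second mechanism. The gene
count is the load-bearing choice: with 3–4 training cases, the Welch
test's degrees of freedom are so low that the genuinely shifted genes'
p-values (~0.02–0.06) are out-ranked by the lucky tail of thousands of
null genes, so the rare finding's top-5% signature is mostly noise and
its own KNN ensemble degrades — the instability severe imbalance causes
in practice — while the strong findings keep clean signatures whose
scores integration can borrow. At small gene counts this failure mode
disappears and both scorers saturate.

## Numerical choices and edge cases

- Expression files are written with 17 significant digits, so a
  write→read cycle is bit-exact for float64; similarity tables are read
  with round-trip float parsing.
- Degenerate threshold selection (all scores identical) returns the
  lowest candidate, calling everything positive.
- `filter_findings` (keep findings induced by ≥ `min_drugs` distinct
  compounds; 5 is the conventional cut for real catalogs) is applied
  only when requested; synthetic studies default to no filter.
- Fold counts exceeding the number of distinct drugs, overlapping
  case/control groups, misaligned sample ids, non-binary occurrence
  cells, and missing thresholds are hard errors, not warnings.

## Known limitations

- Sensitivities at the tuned threshold are noisier than AUCs for rare
  findings: a fold's threshold is tuned on optimistic training scores
  and applied to a handful of test cases.
- Findings untrainable in some folds are evaluated on the remaining
  folds only, so their pooled metrics cover fewer held-out samples.
- The integrative layer is a single linear pass; it cannot correct a
  finding whose neighbors are themselves mispredicted, and it inherits
  false positives from strongly co-occurring findings.
- KNN scoring is O(n_train × n_test) per sub-model; for cohorts far
  beyond ~10⁴ samples a neighbor index would be needed.
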