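# Methods

This note documents the models and procedures implemented in `miescreen`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## MIE label derivation and clustering

Annotation records are (chemical, target, mode, support) tuples, support
being the number of independent literature sources. Records with
unspecified mode are excluded (a chemical with unknown direction cannot be
pooled with activators or inhibitors). Opposing-mode conflicts for the same
chemical–target pair keep the record with the strictly higher support; an
exact tie is treated as uninformative and both records are dropped with a
warning — the strict-maximum rule says nothing about ties, and guessing a
direction would contaminate a training set. Duplicate rows keep the maximum
support. Records below the high-confidence threshold (support ≥ 5, the
level at which such annotations agree well with orthogonal assays) are
retained but flagged: they are never used as training labels, and the 3–4
band ("moderate support") is reserved for the rank-enrichment validation.

MIEs over near-identical chemical sets are merged by hierarchical
clustering on 1 − Jaccard with **complete linkage** (the default of the
standard clustering routine; configurable), cut at height 0.7. Clustering
is performed within mode only — a target's activation and inhibition are
never merged, since every meaningful MIE group carries a single direction.
Cluster display names are generated deterministically: gene symbols with a
shared family prefix collapse to `PREFIX-S1/S2 (mode)` (so
`{ESR1 (-), ESR2 (-)}` becomes `ESR-1/2 (-)`), otherwise symbols are
`/`-joined; suffixes sort numerically when numeric.

## Profiles

Expression values are replicate-collapsed moderated z-scores, features ×
profiles. The pipeline never filters on dose or duration (both are carried
as metadata only); instead, each chemical is capped at **20 randomly
selected profiles per cell line** so prolific chemicals cannot dominate a
training set. The cap is applied once globally per cell line before any
training-set assembly, which keeps the active and inactive pools
symmetric. Features are standardized to mean 0, sample standard deviation 1
(n − 1 denominator) across profiles; constant features map to zero rather
than being dropped, keeping matrix shapes stable. Three feature spaces are
supported: landmark genes only, landmark + inferred genes, and ssGSEA
pathway scores (standardized identically to genes). Randomly selected
capped profiles are fixed once per run by the run seed, not re-drawn per
MIE.

## ssGSEA scores

The pathway score of a gene set in one profile is a rank-based running
sum: genes are walked in descending expression order (ties broken by
original feature order, so scores are deterministic), accumulating an
in-set cumulative fraction with increments ∝ |value|^w (normalized to sum
1) against a uniform out-set fraction. Published single-sample enrichment
variants differ in the weight exponent and in whether the aggregate is the
integral or the supremum of the running difference; both are exposed as
configuration (`weight`, default 0.25; `stat`, default `"integral"`)
rather than asserted as ground truth. At w = 0 the statistic reduces to an
unweighted ECDF difference, which is what the brute-force oracle in the
test suite enumerates. A set covering every measured gene is rejected (the
out-set ECDF is undefined), and a set with all-zero in-set values under a
positive weight falls back to uniform increments.

## Training sets and classifiers

Eligibility: ≥ 5 chemicals at support ≥ 5 and ≥ 50 capped profiles in the
cell line. The inactive pool excludes any chemical annotated to any of the
MIE's targets *at any support level or mode* (a support-3 link is weak
evidence of activity, not evidence of inactivity) and requires a
high-support link to some other MIE (so "inactive" profiles are known
bioactive treatments, not unannotated unknowns). Active and inactive sets
are equal-sized; 20% of each class (floored) is withheld as holdout.

Six algorithm families are trained per MIE: SVM with linear, polynomial
and radial kernels, k-nearest neighbours, a multilayer perceptron limited
to a single hidden layer, and Gaussian naive Bayes. Hyperparameter grids
are small and explicit (SVM cost ∈ {0.25, 0.5, 1}; k ∈ {5, 7, 9}; hidden
layer ∈ {3, 5, 9}; NB variance smoothing ∈ {1e−9, 1e−6} — the Laplace
count-smoothing parameter of categorical naive Bayes has no analogue for
Gaussian features, so the variance regularizer plays that role). Grid
search uses one fixed, seeded, stratified 5-fold assignment for all grid
points; the best point maximizes mean fold accuracy with ties resolved in
grid order; the winner is refit on all training profiles and scored on the
holdout split. Internal accuracy is the mean of the five fold accuracies;
holdout accuracy comes from the refit-on-all-training model. Prediction
scores use class probabilities where the estimator provides them and a
logistic squash of the decision value otherwise; only score *ranks* are
consumed downstream, so any strictly monotone choice is equivalent.

## Replacement nulls and empirical significance

A classifier trained on profiles of a handful of chemicals can look
accurate merely because replicates of one treatment resemble each other.
The null model quantifies this: every active chemical is swapped for a
decoy drawn uniformly from chemicals that are annotated to at least one
other MIE, are not linked to the modelled MIE at any support or mode, and
have at least as many available profiles as the slot requires; the decoy
contributes exactly the slot's profile count, so chemical count and total
profile volume are preserved exactly. Decoys are unique within one null
iteration (sampling without replacement across slots avoids degenerate
nulls), and slots are filled hardest-first so feasible decoys are not
squandered. The inactive side is re-drawn independently per iteration
under the original rules, and training (holdout split, folds, grid) is
identical to the original. The empirical p-value is the proportion of null
internal accuracies **at or above** the original's; ties count toward the
numerator. Candidate high-performance classifiers have p ≤ 0.05; per MIE
the passing algorithm with the highest internal accuracy is selected, with
the polynomial-kernel SVM excluded from selection (its holdout accuracies
degrade relative to internal accuracy, the signature of overfitting).

## Exemplar, percentile-rank and KS validation

Exemplar candidates are the union of each MIE's top 10 chemicals by
support. MIEs are processed in descending order of their best candidate's
support (ties by label — the iteration order is fixed and logged); a
candidate is feasible only if excluding all its profiles, cumulatively
with previously chosen exemplars, leaves *every* modelled MIE with ≥ 5
chemicals and ≥ 50 profiles. A chemical in several candidate lists is
assigned to all those MIEs at once; infeasible MIEs get no exemplar and
are flagged unconfirmable downstream.

Predictions over all profiles of a cell line are collapsed to per-chemical
medians (non-chemical perturbagens and the classifier's own training
chemicals excluded), ranked (1 = highest, ties share the mean rank), and
converted to percentiles by `(n − rank)/(n − 1)` — the convention under
which the top chemical scores exactly 1 and the bottom 0. Confirmation
requires exemplar percentile ≥ 0.90. Moderate-support chemicals (support
3–4, plus the exemplar when available) are tested for enrichment at high
scores with a one-sided two-sample KS test whose statistic is the largest
excess of the background ECDF over the subset ECDF; the background is the
chemical-level median-score distribution by default (profile-level is
supported), matching the chemical-centric ranking.

## Cross-cell-line comparison

MIE-matched internal accuracies from two cell lines are inner-joined,
correlated (Pearson r with its two-sided t-test p), fit by least squares,
and annotated with the accuracy difference. Baseline target expression per
MIE is the median NX value over its target genes; the cross-line contrast
is `log2((NX_a + 0.1)/(NX_b + 0.1))`. Stored values are never capped; any
±4 capping is a plotting convention only. Paired accuracy-vector
comparisons (feature spaces, internal vs holdout) use the Wilcoxon
signed-rank test, returning the degenerate p = 1 when all differences are
zero.

## Synthetic benchmark

The generator plants an additive model: the profile of chemical *c* in
cell line *L* is Σ over the chemical's true MIEs of
`effect_size × responsiveness(L, m) × signature_m` plus i.i.d. Gaussian
noise, on 100 landmark genes; 200 inferred features are a fixed random
linear map of the landmark values plus extra noise. Defaults describe a
desk-scale corpus: 120 chemicals, 8 MIEs × 8 chemicals (paralog pairs get
10), ~8 profiles per chemical per cell line, effect size 2 in z-score
units against noise SD 1, support uniform on 5–30 with a moderate band at
3–4, two cell lines with the first MIE silenced in the second
(`responsiveness = 0`, NX = 0 — the planted cross-cell contrast). These
sizes run the full pipeline including 100-null significance in about a
minute on one CPU, while leaving every eligibility threshold (5 chemicals,
50 profiles) non-trivially binding.

Chemicals exceeding the 20-profile cap are allocated by quota — one per
MIE, round-robin — rather than by independent coin flips. The quota equals
the configured tail probability in expectation and guarantees that every
replacement-null slot can find a volume-matched decoy in another MIE,
which independent draws cannot.

What the generator does **not** emulate: L1000 bead-array noise structure,
replicate-collapse (moderated z-scores are emulated by standardization
itself), dose–response, correlated gene–gene noise, or class imbalance in
the annotation graph. Passing the recovery suite therefore shows that the
pipeline's logic is correct and calibrated under its own assumptions — not
that any particular accuracy level will be attained on real corpora, where
signal-to-noise is far lower and annotations are noisier.

## Numerical conventions

- Holdout size: `floor(0.2 × n)` per class, drawn without replacement.
- Grid ties: first point in grid (insertion) order wins.
- Rank ties: mean rank; ssGSEA rank ties: stable original feature order.
- Standard deviation: always the n − 1 sample form; sd = 0 features map
  to zeros.
- Wilcoxon with all-zero differences: p = 1 by convention.
- Percentile with n < 2 chemicals: error, not NaN.
- All stochastic steps (capping, inactive draws, holdout splits, folds,
  null construction, the generator) consume seeds derived from a single
  run seed via seed sequences, so full runs are bit-reproducible.

## Known limitations

- The exact published ssGSEA variant is not recoverable from its
  description; the weight/aggregation configuration here is a documented
  choice, not a verified reproduction.
- Whether holdout accuracy should come from the refit-on-all-training
  model or the best cross-validation model is ambiguous in the framework
  this mirrors; this package refits.
- Whether nulls should reuse the original inactive set or re-draw it is
  equally open; this package re-draws, which makes the null ensemble
  strictly exchangeable with the original under no signal (the property
  the calibration test checks).
- Feasibility of null construction requires, for every active chemical, a
  volume-matched decoy; corpora with one extreme-volume chemical and no
  peer will error rather than silently under-match.
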