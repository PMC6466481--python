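# Methods

## Data model and exclusion rule

Every stage consumes a `FeatureTable`: an `n × p` real matrix with binary
labels (1 = case, 2 = control; internally re-encoded {1, 0} for
correlation-style computations) and ordered per-feature metadata. Tables
with any missing or non-numeric cell are rejected with the offending
row/column named — the design excludes incomplete records rather than
imputing, to avoid imputation bias in a risk-screening setting. Column
order is canonical: every score, contribution and weight vector is indexed
by it.

## Filter scorers

All six scorers return raw scores, min-max-normalized scores `s ∈ [0, 1]`,
and a descending ranking with ties broken by canonical column order.
Numerical conventions, chosen once and applied everywhere:

- **Unit-interval scaling first.** `std` and `relief` operate on features
  min-max scaled to [0, 1], so spread and distance are comparable across
  measurement units (a balanced binary feature has SD 0.5; the reference
  cohort's largest per-feature SD is 0.21 on this scale).
- **Population (1/n) variance** throughout.
- **Min-max of a constant vector → all zeros** (avoids 0/0 and demotes
  uninformative features).
- **Discretization** for information gain and chi-square: equal-frequency
  binning, 10 bins, fewer when the feature has fewer distinct values. No
  principled binning is implied by the problem; this is the package's
  convention and is deliberately shared by both scorers so they agree on
  the independence null.
- **Fisher degenerate case**: zero within-class variance with distinct
  class means is a perfect separator; its score is capped at 10× the
  largest finite score so it ranks first without propagating infinities.
- **Relief** uses the single nearest hit/miss by Manhattan distance on
  scaled features and, by default, a deterministic full sweep visiting
  every instance once; the classic randomized variant (sampling with
  replacement) is available via `n_iterations` + `seed`. A class with a
  single member has no nearest hit and is rejected.

The spread-based (`std`) scorer never sees the labels. On synthetic
cohorts whose informative features differ between classes only in mean,
it cannot systematically rank them above noise — a pure mean shift barely
changes the min-max-scaled spread. Tests of planted-feature recovery
therefore cover the five label-aware scorers; `std` is validated against
closed forms instead. In the real cohort this scorer was nevertheless a
useful committee member, which the pipeline accommodates: the tournament,
not any single filter, decides who votes.

## Wrapper stage

A filter ranking becomes a prefix-accuracy curve: for each prefix length
`i`, an RBF-SVM is tuned by exhaustive grid search over penalty
`C ∈ {1, 2, 4, 8, 16, 32, 64, 128, 256}` and kernel bandwidth
`q ∈ {0.1, 0.2, 0.3, 0.5, 1, 2, 4, 8}` (the value sets of the reference
tuning run; both are configurable) on mean stratified-CV accuracy
(default 10 folds). Ties prefer the smaller penalty, then the smaller
bandwidth; features are standardized inside each training fold only;
(C, q) are re-tuned independently per prefix. Accuracy is kept at full
precision internally and rounded to 1 dp only in reports.

"Backward searching" is operationalized as incremental prefix evaluation
in descending rank order — the reference accuracy column (56.1 → 57.1 →
58.6 …, with each contribution equal to the consecutive difference) is
only consistent with this reading, not with backward elimination.

Contributions: `raw[i] = acc[i] − acc[i−1]` for ranks ≥ 2; the
first-ranked feature's raw contribution is undefined (NaN). Normalization
min-maxes the defined raws onto [0, 1] — so the most harmful feature gets
0 and the most helpful 1 — and then assigns the first-ranked feature
c = 1.00, copying the printed convention of the reference curve. The
printed "Weight" column of that curve duplicates the raw contribution
column and contradicts its own text definition (s + c); the package
follows the text (`per_model_weight = s + c`) and treats the printed
column as an erratum.

## Voting, assessment, selection

The notation of the source conflates "normalized filter score" and
"normalized wrapper contribution" under one symbol. The printed tables
disambiguate, and the package follows that reconciliation as canonical:
the weight-sum vector `W` sums *scores*; the contribution matrix `C` and
cumulative matrix `D` are *contribution*-based. Under this reading the
shipped fixtures reproduce all printed results: row sums give the printed
weight sums to 4 dp, `W × D` gives the printed coefficients (52, 61, 63)
after integer rounding, and `P × Cᵀ` is consistent with the printed final
weighting (the top feature's weight ≈ 52 + 61 + 63, since it is every
model's top accuracy-contributor). A strict-literal mode is not provided
because it reproduces none of the printed tables.

The tournament starts from the first three models of the fixed catalog
(std, pearson, fisher, infogain, relief, chi2) — or a seeded random trio —
records each active model's coefficient, replaces the smallest-P model
with the next unused candidate, and repeats until the catalog is
exhausted; winners are the three largest recorded coefficients (ties by
catalog order). Note that a model's coefficient `P_m = W · D_m` depends on
which two models are co-active (their scores enter `W`), so coefficients
are context-dependent and the winning set is not, in general, invariant to
catalog order; determinism given a catalog and seed is guaranteed, order
invariance is not claimed.

Selection takes the minimal descending-`W_r` prefix whose cumulative share
strictly exceeds the threshold (default 0.5, per "more than 50%"). Shares
are undefined when every weight is zero (degenerate vote → error).

## Synthetic value and risk surface

`SV = Σ coefficient · raw feature value`, with coefficients the selected
features' min-max weights (top feature 1). The published nine-term stroke
model and its high-risk SV interval (1675, 2175) ship as metadata; the
interval is a property of the reference cohort's fitted surface and is not
recomputed.

The risk surface is the empirical case frequency on a 46 age-bin × 50
SV-bin grid (ages 45–90), smoothed by normalized Gaussian convolution
(default bandwidths 1.5 grid cells per axis) plus `prior_count = 10`
pseudo-observations at the overall case rate. The shrinkage term is the
package's convention: without it a lone subject in a sparse corner cell
pins the smoothed frequency at 0 or 1, and no pure convolution bandwidth
makes a label-permuted cohort's surface flat on this grid. The mapping of
frequency to the banded risk-index scale is likewise a documented
convention — frequency × 3, so 0.5 sits at the none/low boundary (1.5)
and 2/3 at the low/high boundary (2.0). Band semantics on real data
therefore depend on this calibration choice; the surface is qualitative.

## Evaluation

Cross-validated evaluations pool out-of-fold confusion counts (micro
pooling), so accuracy is exactly `(tp + tn)/n` and integer counts are
reportable. Baseline filters in `compare_methods` choose their own feature
count at the peak of their prefix-accuracy curve on the same CV used for
reporting — optimistically biased, and kept deliberately because the
comparison harness mirrors the reference protocol. No nested CV is
performed.

## Synthetic cohorts

`generate_synthetic_cohort` emulates a complete clinical table:
informative features are class-conditionally Gaussian with means separated
by `effect_size` pooled SDs; noise features are identically distributed in
both classes; every feature is affinely dressed into a plausible clinical
range (enzyme-, lipid-, creatinine-, glucose-, protein-like spans) and
integer-kind features are rounded. Defaults mirror the reference cohort's
shape: 792 subjects, 9 informative + 19 noise features, effect size 1.0,
class balance 398/792. The generator does **not** emulate feature
correlations, skewed or heavy-tailed laboratory distributions, age
structure, or label noise — so passing tests demonstrate correct mechanics
and planted-signal recovery, not performance on real clinical data.

## Problem sizes and determinism

Statistical tests run at the sizes stated in their bodies (cohorts of
200–800 subjects, 5–20 features, 20 seeds where a rate is asserted), with
a reduced tuning grid (C ∈ {1, 64}, q ∈ {0.1, 1}) and 3–5 folds — chosen
as the package's own test-scale configuration; the full grids remain the
library defaults. All randomness flows through explicit seeds
(`numpy.random.default_rng`, stratified folds via seeded shuffling), so
every reported number is reproducible.

## Known limitations

- The >50% cumulative-share rule interacts with the concavity of prefix
  accuracy curves: when a few features carry most of the accuracy, the
  selected subset can be smaller than the full planted informative set
  even though every selected feature is informative (high precision,
  incomplete recall). See the acceptance suite for a quantified instance.
- Effectiveness coefficients are context-dependent (above), so tournament
  outcomes can depend on catalog order when candidate models are of
  similar quality.
- The information-gain/chi-square binning and the risk-index calibration
  are conventions; alternative choices yield different absolute scores
  (rankings are typically stable).
- CBA, BPNN and ELM classifiers are not implemented; the classifier
  registry accepts plug-ins behind the same (C, q) factory interface
  (rbf-svm mandatory, gaussian-nb and cart included).
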