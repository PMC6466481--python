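# wrhfs — weighting- and ranking-based hybrid feature selection

`wrhfs` implements a hybrid filter/wrapper feature-selection method for
binary clinical risk detection on complete numeric cohort tables (rows =
subjects, columns = named features plus one binary label, 1 = case,
2 = control). It was built around the ischemic-stroke setting — a cohort of
blood-test and demographic features — but the machinery is generic: any
two-class tabular problem where you want a small, interpretable set of risk
factors plus a scalar risk score.

## The method

Six candidate **filter models** score and rank the `p` features: standard
deviation (on min-max-scaled values), |Pearson r| with the label, Fisher
score, information gain (bits, equal-frequency binning), Relief (nearest
hit/miss on scaled features), and the chi-square statistic.

For a trio of filters the **wrapper stage** turns each ranking into a
prefix-accuracy curve: a grid-tuned RBF-SVM (penalty C, kernel bandwidth q,
standardized inside each training fold) is cross-validated on the top-1,
top-2, …, top-p ranked features. The *accuracy contribution* of a feature
is the change in CV accuracy when it joins the prefix; contributions are
min-max-normalized to `c ∈ [0, 1]` (the first-ranked feature is assigned
c = 1 by convention).

The **voting and assessment stage** fuses the trio:

- `S` (p×3): normalized filter scores; `W = Σ_m s_m` (weight-sum vector);
- `C` (p×3): normalized contributions; `D` (p×3): cumulative contributions
  in each model's own rank order;
- effectiveness coefficients `P = W × D` — one scalar per filter model;
- a tournament repeatedly replaces the lowest-P model with the next
  candidate until the catalog is exhausted, keeping the three models with
  the largest coefficients;
- final feature weights `W_r = P × Cᵀ`, and the selected subset is the
  minimal descending-weight prefix whose cumulative share of `Σ W_r`
  strictly exceeds 50%.

Downstream, the selected features define a **synthetic value**
`SV = Σ w01_f · x_f` (min-max weights as coefficients, top feature 1) and
an empirical age × SV risk surface with three bands (index ≤ 1.5 none,
≤ 2 low, > 2 high).

Classification quality is reported as sensitivity, specificity, accuracy
(pooled out-of-fold confusion counts) and the Youden index
(sensitivity + specificity − 1).

## Worked example

`examples/03_full_selection.py` generates a 300-subject cohort with two
planted informative features among four pure-noise features and runs the
full pipeline:

```
effectiveness coefficients (last recorded per model):
        std:  12.85  <- winner
   infogain:   9.40  <- winner
       chi2:   9.40  <- winner
     relief:   9.28
     fisher:   8.93
    pearson:   8.85

   feature   weight  share    cum   w01  selected
    inf_02    39.09  0.360  0.360  1.00  True
    inf_01    29.35  0.270  0.630  0.75  True
  noise_01    21.40  0.197  0.827  0.54  False
  ...
selected 2 features; planted informative set: ['inf_01', 'inf_02']
```

The two planted features carry the largest final weights and are exactly
the selected subset: the cumulative share passes 50% at the second feature
(0.630), so N = 2. The other examples cover filter scoring
(`01_filter_scores.py`), the prefix-accuracy curve (`02_prefix_curve.py`),
and SV risk scoring with the published nine-term model
(`04_risk_index.py`).

A thin CLI mirrors the library: `wrhfs scores | curve | select | evaluate |
compare | riskmap | simulate | verify-fixtures` (see `wrhfs --help`).

## Reference tables

The package ships the printed tables of the reference stroke study as
read-only CSV fixtures (`wrhfs.fixtures`): per-model effectiveness
coefficients, the standard-deviation model's prefix curve, the score and
contribution/cumulative matrices, the final 28-feature weighting, and the
SVM comparison metrics. `wrhfs verify-fixtures` (or
`wrhfs.fixtures.verify_fixtures()`) recomputes the voting arithmetic on
them and fails loudly on any inconsistency.

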