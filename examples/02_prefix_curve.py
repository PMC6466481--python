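"""Turn one filter ranking into a prefix-accuracy curve and contributions.

Ranks features by |Pearson r|, then trains a grid-tuned RBF-SVM on each
prefix of the ranking (top-1, top-2, ...) under stratified cross-validation.
The per-feature contribution is the accuracy change when that feature joins
the prefix; its min-max normalization (first-ranked feature assigned 1.00)
is what the voting stage aggregates.
"""

import numpy as np

from wrhfs import ClassifierConfig, SyntheticSpec, generate_synthetic_cohort, prefix_accuracy_curve, score

table, informative = generate_synthetic_cohort(
    SyntheticSpec(n_samples=300, n_informative=2, n_noise=4, effect_size=1.5, seed=7)
)
config = ClassifierConfig(penalty_grid=(1, 16, 256), bandwidth_grid=(0.1, 1, 8), cv_folds=5, seed=0)

sv = score(table, "pearson")
curve = prefix_accuracy_curve(table, sv, config)

pos = {f: i for i, f in enumerate(curve.feature_names)}
print(f"{'rank':>4} {'feature':>10} {'C':>4} {'q':>4} {'acc %':>6} {'contrib':>8} {'c01':>5}")
for r, feat in enumerate(curve.ordered_features):
    C, q = curve.tuned_params[r]
    raw = curve.raw_contribution[pos[feat]]
    print(
        f"{r + 1:>4} {feat:>10} {C:>4g} {q:>4g} {curve.prefix_accuracy[r]:>6.1f} "
        f"{'—' if np.isnan(raw) else f'{raw:+.2f}':>8} {curve.c[pos[feat]]:>5.2f}"
    )

print(
    "\nAccuracy climbs while informative features join the prefix and then\n"
    "plateaus; noise features contribute ~0 and receive small normalized c."
)
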