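"""Read-only access to the published reference tables shipped with the package.

These small CSVs hold the printed numbers of the reference stroke-cohort
study (filter effectiveness coefficients, the standard-deviation model's
prefix-accuracy curve, the three normalized score vectors with their weight
sum, the contribution and cumulative-contribution matrices, the final
feature weighting, and the SVM comparison metrics). They serve two
purposes: exact verification of the voting arithmetic, and worked examples.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

#: catalog order of the candidate filter models (also the tie-break order)
MODEL_CATALOG = ("std", "pearson", "fisher", "infogain", "relief", "chi2")

#: the three winning filter models, in the column order used by the
#: score/contribution matrices below
WINNING_MODELS = ("std", "relief", "infogain")

#: published risk-score coefficients: feature -> weight01 coefficient
SV_COEFFICIENTS = {
    "Age": 1.0,
    "α-HBD": 0.42,
    "SCr": 0.38,
    "LDH": 0.30,
    "Height": 0.30,
    "TBIL": 0.27,
    "CK": 0.22,
    "Apo-B": 0.20,
    "CK-MB": 0.19,
}

#: published high-risk interval of the synthetic value, in SV units
HIGH_RISK_INTERVAL = (1675.0, 2175.0)


def _load(name: str) -> pd.DataFrame:
    with resources.files("wrhfs.tables").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def effectiveness_coefficients() -> pd.DataFrame:
    """Published per-model effectiveness coefficients (integers)."""
    return _load("effectiveness_coefficients.csv")


@lru_cache(maxsize=None)
def sd_model_curve() -> pd.DataFrame:
    """The standard-deviation model's published prefix curve.

    Columns: feature (in SD-rank order), sd, tuned C and q, prefix accuracy
    (%), raw contribution, normalized sd and contribution, and the printed
    weight column. The first-ranked feature's raw contribution is NaN
    (undefined: there is no shorter prefix to compare against).
    """
    return _load("sd_model_curve.csv")


@lru_cache(maxsize=None)
def model_scores() -> pd.DataFrame:
    """Normalized score vectors of the three winning models + weight sum."""
    return _load("model_scores.csv")


@lru_cache(maxsize=None)
def contribution_matrices() -> pd.DataFrame:
    """Per-feature contribution (c_*) and cumulative-contribution (d_*) columns."""
    return _load("contribution_matrices.csv")


@lru_cache(maxsize=None)
def final_weights() -> pd.DataFrame:
    """Published final feature weighting, sorted by decreasing weight."""
    return _load("final_weights.csv")


@lru_cache(maxsize=None)
def svm_comparison() -> pd.DataFrame:
    """Published SVM metrics per feature-selection method (counts and %)."""
    return _load("svm_comparison.csv")


@lru_cache(maxsize=None)
def blood_panel() -> pd.DataFrame:
    """The 24-item blood panel: name, full name, unit, value kind."""
    return _load("blood_panel.csv")


def verify_fixtures(atol_weight_sum: float = 1e-4) -> dict[str, float]:
    """Cross-check the printed tables against the voting arithmetic.

    Returns a dict of measured discrepancies; raises ``AssertionError`` on
    any inconsistency beyond printed rounding. Checked:

    * weight-sum column equals the row sum of the three score columns
      (within one unit in the last printed digit);
    * the effectiveness coefficients of the three winning models are the
      (rounded) dot products of the weight-sum vector with the cumulative
      columns;
    * final-weight shares sum to 1 and select 9 features at the >50% rule.
    """
    from .engine import aggregate_weight_sum, effectiveness

    scores = model_scores()
    S = scores[["std", "relief", "infogain"]].to_numpy()
    W = aggregate_weight_sum(S)
    err_w = float(np.abs(W - scores["weight_sum"].to_numpy()).max())
    assert err_w <= atol_weight_sum + 1e-9, f"weight-sum mismatch: {err_w}"

    mats = contribution_matrices().set_index("feature")
    mats = mats.loc[scores["feature"]]
    D = mats[["d_std", "d_relief", "d_infogain"]].to_numpy()
    P = effectiveness(W, D)
    coeffs = effectiveness_coefficients().set_index("method")["coefficient"]
    expected = np.array([coeffs[m] for m in WINNING_MODELS], dtype=float)
    err_p = float(np.abs(np.round(P) - expected).max())
    assert err_p == 0, f"effectiveness coefficients mismatch: {P} vs {expected}"

    w8 = final_weights()["weight"].to_numpy()
    shares = w8 / w8.sum()
    n_sel = int(np.argmax(np.cumsum(shares) > 0.5) + 1)
    assert n_sel == 9, f"top-N selection on printed weights gave {n_sel}"
    return {"weight_sum_max_err": err_w, "coefficient_max_err": err_p, "n_selected": n_sel}
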