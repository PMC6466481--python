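"""Synthetic-value (SV) risk scoring, risk bands, and the age x SV surface.

The SV is a linear combination of a subject's selected feature values
(raw clinical units) with their normalized weights; the top feature's
coefficient is 1 by construction of the min-max weight scale. Risk bands
on the risk-index scale: index <= 1.5 -> no risk, 1.5 < index <= 2 -> low
risk, index > 2 -> high risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data import CASE_LABEL, FeatureTable
from .engine import FeatureWeighting
from .fixtures import HIGH_RISK_INTERVAL, SV_COEFFICIENTS

#: thresholds of the three-band rule on the risk-index scale
RISK_THRESHOLDS = (1.5, 2.0)

#: the risk index spans [0, RISK_SCALE]; an empirical case frequency of 1
#: maps to the top of the scale, so frequency 0.5 sits at the no/low-risk
#: boundary (1.5) and 2/3 at the low/high boundary (2.0)
RISK_SCALE = 3.0


@dataclass
class RiskModel:
    """Ordered (feature, coefficient) terms plus band metadata.

    Coefficients are the selected features' min-max weights (top feature
    1.0). ``hri`` is the published high-risk SV interval kept as metadata
    of the reference cohort's fitted model, not recomputed here.
    """

    sv_terms: list[tuple[str, float]]
    hri: tuple[float, float] = HIGH_RISK_INTERVAL
    risk_thresholds: tuple[float, float] = RISK_THRESHOLDS
    surface: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if any(not 0 <= c <= 1 for _, c in self.sv_terms):
            raise ValueError("SV coefficients must lie in [0, 1]")
        if self.hri[0] >= self.hri[1]:
            raise ValueError("high-risk interval must have lower < upper")
        if not self.risk_thresholds[0] < self.risk_thresholds[1]:
            raise ValueError("risk thresholds must be increasing")

    @classmethod
    def from_weighting(cls, weighting: FeatureWeighting) -> "RiskModel":
        """Build SV terms from a WRHFS weighting's selected features."""
        w01 = dict(zip(weighting.feature_names, weighting.weight01))
        return cls(sv_terms=[(f, float(w01[f])) for f in weighting.selected])

    @classmethod
    def published(cls) -> "RiskModel":
        """The reference stroke model's nine published SV terms."""
        return cls(sv_terms=list(SV_COEFFICIENTS.items()))


def synthetic_value(sample: Mapping[str, float], model: RiskModel) -> float:
    """SV = sum over terms of coefficient x raw feature value."""
    total = 0.0
    for feat, coef in model.sv_terms:
        if feat not in sample:
            raise KeyError(f"sample is missing SV term feature {feat!r}")
        total += coef * float(sample[feat])
    return total


def synthetic_values(table: FeatureTable, model: RiskModel) -> np.ndarray:
    """Vectorized SV for every row of a feature table."""
    sv = np.zeros(table.n_samples)
    for feat, coef in model.sv_terms:
        sv += coef * table.column(feat)
    return sv


def risk_rank(index: float, thresholds: tuple[float, float] = RISK_THRESHOLDS) -> str:
    """Band a risk-index value: none (<= t1), low (<= t2), high (> t2)."""
    if not np.isfinite(index):
        raise ValueError("risk index must be finite")
    t1, t2 = thresholds
    if index <= t1:
        return "none"
    if index <= t2:
        return "low"
    return "high"


def risk_surface(
    table: FeatureTable,
    model: RiskModel,
    age_feature: str = "AGE",
    age_range: tuple[float, float] = (45.0, 90.0),
    n_age_bins: int = 46,
    n_sv_bins: int = 50,
    smoothing: tuple[float, float] = (1.5, 1.5),
    prior_count: float = 10.0,
) -> pd.DataFrame:
    """Empirical, kernel-smoothed case frequency on an age x SV grid.

    Each grid cell holds the class-1 (case) frequency of the samples
    falling in it; a Gaussian kernel (bandwidths in grid cells, age then
    SV) smooths case and total counts separately (normalized convolution),
    and ``prior_count`` pseudo-observations at the overall case rate
    shrink sparse cells toward that rate so a lone subject in a corner
    cell cannot pin the frequency at 0 or 1. The smoothed frequency in
    [0, 1] is rescaled to the risk-index scale [0, RISK_SCALE] so the
    banding thresholds apply. Deterministic.

    Returns a tidy frame: age_bin, sv_bin (bin centers), frequency,
    risk_index, band.
    """
    age = table.column(age_feature)
    sv = synthetic_values(table, model)
    is_case = (table.labels == CASE_LABEL).astype(float)

    age_edges = np.linspace(*age_range, n_age_bins + 1)
    sv_edges = np.linspace(sv.min(), sv.max() + 1e-9, n_sv_bins + 1)
    cases, _, _ = np.histogram2d(age, sv, bins=[age_edges, sv_edges], weights=is_case)
    totals, _, _ = np.histogram2d(age, sv, bins=[age_edges, sv_edges])
    if totals.sum() == 0:
        raise ValueError("no samples fall inside the surface grid")

    sm_cases = gaussian_filter(cases, sigma=smoothing, mode="constant")
    sm_totals = gaussian_filter(totals, sigma=smoothing, mode="constant")
    base_rate = is_case.mean()
    freq = (sm_cases + prior_count * base_rate) / (sm_totals + prior_count)
    freq = np.clip(freq, 0.0, 1.0)

    age_centers = (age_edges[:-1] + age_edges[1:]) / 2
    sv_centers = (sv_edges[:-1] + sv_edges[1:]) / 2
    rows = []
    for i, a in enumerate(age_centers):
        for j, s in enumerate(sv_centers):
            ri = RISK_SCALE * freq[i, j]
            rows.append((a, s, freq[i, j], ri, risk_rank(ri, model.risk_thresholds)))
    return pd.DataFrame(
        rows, columns=["age_bin", "sv_bin", "frequency", "risk_index", "band"]
    )
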